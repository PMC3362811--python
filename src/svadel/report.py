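"""Aggregate deletion calls into headline statistics and render reports.

Per event type (SRAD / SIMD): count, total deleted bp, size range, mean size
(exact, plus a half-up integer display value), mechanism, subfamily and
breakpoint-segment tallies; plus the combined deleted total in kb at one
decimal.  Works on pipeline calls or on the packaged result-table fixture.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Union

from .annotate import tabulate_breakpoint_positions, tabulate_segment_codes
from .core import DeletionCall, EventType, Mechanism, SvaSegment
from .io import PaperFixture, load_paper_fixture


def _round_half_up(value: float) -> int:
    return int(Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _kb_half_up(bp: int) -> str:
    return str((Decimal(bp) / 1000).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EventSummary:
    count: int
    total_bp: int
    min_bp: int
    max_bp: int
    mean_bp: float           # exact value
    mean_bp_display: int     # half-up integer, for printing
    mechanism_counts: Dict[str, int] = field(default_factory=dict)
    subfamily_counts: Dict[str, int] = field(default_factory=dict)
    segment_code_counts: Dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class Summary:
    srad: EventSummary
    simd: EventSummary
    combined_total_bp: int
    combined_kb_display: str


def _empty_event_summary() -> EventSummary:
    return EventSummary(0, 0, 0, 0, 0.0, 0)


def _summarize_sizes(sizes: List[int]) -> tuple:
    if not sizes:
        return 0, 0, 0, 0, 0.0, 0
    total = sum(sizes)
    mean = total / len(sizes)
    return len(sizes), total, min(sizes), max(sizes), mean, _round_half_up(mean)


def summarize_calls(source: Union[Sequence[DeletionCall], PaperFixture]) -> Summary:
    """Build a Summary from pipeline calls or from the packaged fixture tables."""
    if isinstance(source, PaperFixture):
        return _summarize_fixture(source)
    calls = list(source)
    if not calls:
        raise ValueError("no calls to summarize")
    by_type: Dict[EventType, List[DeletionCall]] = {EventType.SRAD: [], EventType.SIMD: []}
    for call in calls:
        by_type[call.event_type].append(call)

    summaries = {}
    for etype, group in by_type.items():
        sizes = [c.deletion_size for c in group]
        count, total, mn, mx, mean, mean_disp = _summarize_sizes(sizes)
        mech = Counter(c.mechanism.value for c in group
                       if c.mechanism != Mechanism.NA)
        codes = tabulate_breakpoint_positions(group) if etype == EventType.SRAD else {}
        summaries[etype] = EventSummary(
            count, total, mn, mx, mean, mean_disp,
            mechanism_counts=dict(sorted(mech.items())),
            subfamily_counts={},
            segment_code_counts={int(k): v for k, v in codes.items() if v},
        )
    combined = summaries[EventType.SRAD].total_bp + summaries[EventType.SIMD].total_bp
    return Summary(summaries[EventType.SRAD], summaries[EventType.SIMD],
                   combined, _kb_half_up(combined))


def _summarize_fixture(fixture: PaperFixture) -> Summary:
    srad_sizes = [r.deletion_size for r in fixture.srad_rows]
    simd_sizes = [r.deletion_size for r in fixture.simd_rows]
    mech = Counter(r.mechanism_label for r in fixture.srad_rows)
    codes = tabulate_segment_codes(
        [(r.left_code, r.right_code) for r in fixture.breakpoint_rows])
    count, total, mn, mx, mean, mean_disp = _summarize_sizes(srad_sizes)
    srad = EventSummary(count, total, mn, mx, mean, mean_disp,
                        mechanism_counts=dict(sorted(mech.items())),
                        segment_code_counts={int(k): v for k, v in codes.items() if v})
    count, total, mn, mx, mean, mean_disp = _summarize_sizes(simd_sizes)
    simd = EventSummary(count, total, mn, mx, mean, mean_disp)
    combined = srad.total_bp + simd.total_bp
    return Summary(srad, simd, combined, _kb_half_up(combined))


def summarize_paper_fixture() -> Summary:
    return summarize_calls(load_paper_fixture())


# ---------------------------------------------------------------------------
# rendering

def summary_to_dict(summary: Summary) -> dict:
    def ev(e: EventSummary) -> dict:
        return {
            "count": e.count, "total_bp": e.total_bp,
            "min_bp": e.min_bp, "max_bp": e.max_bp,
            "mean_bp": e.mean_bp, "mean_bp_display": e.mean_bp_display,
            "mechanism_counts": dict(e.mechanism_counts),
            "subfamily_counts": dict(e.subfamily_counts),
            "segment_code_counts": {str(k): v for k, v in e.segment_code_counts.items()},
        }
    return {
        "srad": ev(summary.srad),
        "simd": ev(summary.simd),
        "combined_total_bp": summary.combined_total_bp,
        "combined_kb_display": summary.combined_kb_display,
    }


def summary_from_dict(data: dict) -> Summary:
    def ev(d: dict) -> EventSummary:
        return EventSummary(
            d["count"], d["total_bp"], d["min_bp"], d["max_bp"],
            d["mean_bp"], d["mean_bp_display"],
            mechanism_counts=dict(d.get("mechanism_counts", {})),
            subfamily_counts=dict(d.get("subfamily_counts", {})),
            segment_code_counts={int(k): v for k, v in
                                 d.get("segment_code_counts", {}).items()},
        )
    return Summary(ev(data["srad"]), ev(data["simd"]),
                   data["combined_total_bp"], data["combined_kb_display"])


def render_report(summary: Summary, format: str = "markdown") -> str:
    """Serialize a summary as tsv, markdown or json (deterministic)."""
    if format == "json":
        return json.dumps(summary_to_dict(summary), indent=2, sort_keys=True) + "\n"
    if format == "tsv":
        lines = ["event_type\tcount\ttotal_bp\tmin_bp\tmax_bp\tmean_bp_display\tmechanisms"]
        for name, e in (("SRAD", summary.srad), ("SIMD", summary.simd)):
            mech = ",".join(f"{k}:{v}" for k, v in sorted(e.mechanism_counts.items()))
            lines.append(f"{name}\t{e.count}\t{e.total_bp}\t{e.min_bp}\t{e.max_bp}"
                         f"\t{e.mean_bp_display}\t{mech}")
        lines.append(f"combined\t\t{summary.combined_total_bp}\t\t\t\t"
                     f"{summary.combined_kb_display} kb")
        return "\n".join(lines) + "\n"
    if format == "markdown":
        return _render_markdown(summary)
    raise ValueError(f"unknown report format {format!r}")


def _render_markdown(summary: Summary) -> str:
    lines = ["# SVA-associated deletion summary", ""]
    for name, e in (("SRAD", summary.srad), ("SIMD", summary.simd)):
        lines += [f"## {name}", ""]
        lines += [
            f"- loci: {e.count}",
            f"- total deleted: {e.total_bp} bp",
            f"- size range: {e.min_bp}-{e.max_bp} bp",
            f"- mean size: {e.mean_bp_display} bp",
        ]
        if e.mechanism_counts:
            mech = ", ".join(f"{k} {v}" for k, v in sorted(e.mechanism_counts.items()))
            lines.append(f"- mechanisms: {mech}")
        if e.segment_code_counts:
            seg = ", ".join(f"code {k}: {v}"
                            for k, v in sorted(e.segment_code_counts.items()))
            lines.append(f"- SVA breakpoint segments: {seg}")
        lines.append("")
    lines.append(f"**Combined deleted sequence: {summary.combined_kb_display} kb "
                 f"({summary.combined_total_bp} bp)**")
    return "\n".join(lines) + "\n"
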