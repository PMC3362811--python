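"""Decide whether an aligned locus pair carries an SRAD, a SIMD, or nothing.

An SRAD candidate is a derived-side alignment gap (sequence present in the
ancestral genome, absent from the derived one) whose ancestral footprint
removes part of an SVA element *and* adjacent non-SVA sequence (or parts of
two elements).  A SIMD candidate is ancestral-only sequence remaining at the
insertion point of a derived-specific SVA after the inserted element itself
is masked out, with no target-site duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .core import DeletionCall, EventType, GenomicInterval, Mechanism, RepeatFeature
from .ortholog import Gap, LocusPair

logger = logging.getLogger(__name__)

DEFAULT_MIN_SRAD_BP = 50   # excludes alignment jitter
DEFAULT_MIN_SIMD_BP = 1    # a 14 bp target deletion is real and reported
# matched islands up to this width are smoothed over; a deletion ending in a
# tandem-repeat tract (e.g. the SVA VNTR, ~40 bp unit) fragments into gap
# pieces separated by islands of up to one repeat unit once substitutions
# make shifted placements locally optimal
DEFAULT_MERGE_BP = 50


@dataclass(frozen=True)
class MergedGap:
    """One or more query-side gaps merged across small matched islands."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    ancestral_bp: int  # target bases missing from the query (gap bases only)
    n_gaps: int

    @property
    def net_bp(self) -> int:
        """Net ancestral excess over the window: exact deleted length even
        when the gap is fragmented across a repeat tract."""
        return (self.t_end - self.t_start) - (self.q_end - self.q_start)


def merge_query_gaps(gaps: Sequence[Gap], merge_bp: int = DEFAULT_MERGE_BP) -> List[MergedGap]:
    """Merge derived-side (query) gaps separated by <= ``merge_bp`` aligned bases."""
    qgaps = sorted((g for g in gaps if g.side == "query"), key=lambda g: g.t_start)
    merged: List[MergedGap] = []
    for g in qgaps:
        glen = g.t_end - g.t_start
        if merged:
            last = merged[-1]
            island_t = g.t_start - last.t_end
            island_q = g.q_start - last.q_end
            if 0 <= island_t <= merge_bp and 0 <= island_q <= merge_bp:
                merged[-1] = MergedGap(last.q_start, g.q_end, last.t_start, g.t_end,
                                       last.ancestral_bp + glen, last.n_gaps + 1)
                continue
        merged.append(MergedGap(g.q_start, g.q_end, g.t_start, g.t_end, glen, 1))
    return merged


def _sva_features(features: Sequence[RepeatFeature], seq_id: str) -> List[RepeatFeature]:
    return [f for f in features if f.is_sva and f.interval.seq_id == seq_id]


def call_srad(
    pair: LocusPair,
    derived_annotations: Sequence[RepeatFeature],
    ancestral_annotations: Sequence[RepeatFeature],
    min_deletion_bp: int = DEFAULT_MIN_SRAD_BP,
    merge_bp: int = DEFAULT_MERGE_BP,
    ancestral_seq: Optional[str] = None,
) -> Optional[DeletionCall]:
    """Call an SVA recombination-associated deletion on a shared-SVA locus.

    Returns a call iff some merged derived-side gap of length
    >= ``min_deletion_bp`` has an ancestral footprint overlapping both SVA and
    non-SVA sequence (or two distinct SVA elements).  ``ancestral_seq`` (the
    target locus sequence, local coordinates) enables the unsequenced-region
    check: deletions overlapping N runs are flagged ``indeterminate_size``.
    """
    t_off = pair.target_interval.start
    q_off = pair.query_interval.start
    seq_id_t = pair.target_interval.seq_id
    svas = _sva_features(ancestral_annotations, seq_id_t)

    candidates = []
    for mg in merge_query_gaps(pair.gaps, merge_bp):
        if mg.net_bp < min_deletion_bp:
            continue
        span = GenomicInterval(seq_id_t, t_off + mg.t_start, t_off + mg.t_end)
        if not pair.target_interval.contains(span):
            raise ValueError(f"gap {span} outside aligned locus {pair.target_interval}")
        sva_overlap = sum(f.interval.overlap_length(span) for f in svas)
        n_sva = sum(1 for f in svas if f.interval.overlap_length(span) > 0)
        non_sva = span.length() - sva_overlap
        if sva_overlap > 0 and (non_sva > 0 or n_sva >= 2):
            candidates.append((mg, span))
    if not candidates:
        return None
    # one event per locus: keep the largest, flag any extras
    candidates.sort(key=lambda c: c[0].net_bp, reverse=True)
    mg, span = candidates[0]
    flags = []
    if len(candidates) > 1:
        flags.append("multiple_gaps")
    if mg.n_gaps > 1:
        # fragmented placement in a repeat tract: report the net deleted
        # length anchored at the leftmost gap edge
        flags.append(f"merged_{mg.n_gaps}_gaps")
        logger.info("%s: merged %d gap pieces into one deletion", pair.locus_id, mg.n_gaps)
    if ancestral_seq is not None and "N" in ancestral_seq[mg.t_start:mg.t_end].upper():
        flags.append("indeterminate_size")
    deleted = GenomicInterval(seq_id_t, span.start, span.start + mg.net_bp)
    junction = GenomicInterval(pair.query_interval.seq_id,
                               q_off + mg.q_start, q_off + mg.q_start)
    return DeletionCall(
        event_type=EventType.SRAD,
        locus_id=pair.locus_id,
        derived_junction=junction,
        ancestral_deleted=deleted,
        deletion_size=mg.net_bp,
        mechanism=Mechanism.NA,
        flags=tuple(flags),
    )


def call_simd(
    pair: LocusPair,
    insertion_local: GenomicInterval,
    derived_locus_seq: str,
    min_deletion_bp: int = DEFAULT_MIN_SIMD_BP,
    merge_bp: int = DEFAULT_MERGE_BP,
    max_tsd_bp: int = 20,
    junction_window: int = 50,
    ancestral_seq: Optional[str] = None,
) -> Tuple[Optional[DeletionCall], int]:
    """Call an SVA insertion-mediated deletion on a derived-specific-SVA locus.

    ``pair`` must be the alignment of the derived locus with the inserted SVA
    masked out (excised), so that ancestral-only sequence at the insertion
    point shows up as a clean query-side gap.  ``insertion_local`` is the SVA
    interval in the *unmasked* derived locus (local coordinates, used for the
    target-site-duplication check); in masked coordinates the insertion point
    is ``insertion_local.start``.

    Returns ``(call_or_none, tsd_bp)``; a detected TSD of the usual TPRT kind
    marks a clean insertion and is reported alongside.
    """
    ins_point = insertion_local.start
    tsd_bp = detect_tsd(derived_locus_seq, insertion_local, max_tsd_bp)

    t_off = pair.target_interval.start
    total = 0
    t_lo = t_hi = None
    for mg in merge_query_gaps(pair.gaps, merge_bp):
        if abs(mg.q_start - ins_point) <= junction_window:
            total += mg.net_bp
            t_lo = mg.t_start if t_lo is None else min(t_lo, mg.t_start)
            t_hi = mg.t_end if t_hi is None else max(t_hi, mg.t_end)
    if t_lo is None or total < min_deletion_bp:
        return None, tsd_bp

    flags = []
    if tsd_bp > 0:
        flags.append(f"tsd_{tsd_bp}bp")
    if ancestral_seq is not None and "N" in ancestral_seq[t_lo:t_hi].upper():
        flags.append("indeterminate_size")
    footprint = GenomicInterval(pair.target_interval.seq_id, t_off + t_lo, t_off + t_lo + total)
    derived_iv = GenomicInterval(
        pair.query_interval.seq_id,
        pair.query_interval.start + insertion_local.start,
        pair.query_interval.start + insertion_local.end,
    )
    call = DeletionCall(
        event_type=EventType.SIMD,
        locus_id=pair.locus_id,
        derived_junction=derived_iv,
        ancestral_deleted=footprint,
        deletion_size=footprint.length(),
        mechanism=Mechanism.NA,
        flags=tuple(flags),
    )
    return call, tsd_bp


def detect_tsd(derived_seq: str, insertion_interval: GenomicInterval,
               max_tsd_bp: int = 20, min_tsd_bp: int = 5) -> int:
    """Longest exact direct repeat (>= ``min_tsd_bp``) flanking an insertion, else 0.

    N bases never match.  ``max_tsd_bp`` is capped at 50.
    """
    if max_tsd_bp > 50:
        raise ValueError("max_tsd_bp must be <= 50")
    s, e = insertion_interval.start, insertion_interval.end
    if not (0 <= s <= e <= len(derived_seq)):
        raise ValueError("insertion interval outside sequence")
    best = 0
    for k in range(min_tsd_bp, max_tsd_bp + 1):
        if s - k < 0 or e + k > len(derived_seq):
            break
        left = derived_seq[s - k:s].upper()
        right = derived_seq[e:e + k].upper()
        if left == right and "N" not in left:
            best = k
    return best
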