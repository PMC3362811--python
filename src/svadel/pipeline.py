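"""End-to-end orchestration: detect -> classify -> annotate -> context -> summarize.

The detection driver walks the derived genome's SVA annotations.  For each
element it extracts the locus with flanking sequence, anchors the orthologous
ancestral region (k-mer seeding + chaining), and routes the locus to the
SRAD screen (element shared with the ancestral genome) or the SIMD screen
(derived-specific element, aligned with the insertion masked out).  Loci
whose flanks cannot be anchored are reported as unmappable rather than
silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .align import AlignParams
from .calling import (
    DEFAULT_MERGE_BP,
    DEFAULT_MIN_SIMD_BP,
    DEFAULT_MIN_SRAD_BP,
    call_simd,
    call_srad,
)
from .core import DeletionCall, GenomicInterval, RepeatFeature, SVAElement
from .mechanism import DEFAULT_NAHR_MIN_HOMOLOGY, classify_calls
from .annotate import annotate_calls
from .ortholog import (
    DEFAULT_ANCHOR_K,
    DEFAULT_MIN_ANCHOR_IDENTITY,
    FLANK_BP_SIMD,
    FLANK_BP_SRAD,
    GenomeKmerIndex,
    anchor_ortholog,
    build_locus_pair,
)

logger = logging.getLogger(__name__)


@dataclass
class DetectParams:
    align: AlignParams = field(default_factory=AlignParams)
    anchor_k: int = DEFAULT_ANCHOR_K
    min_anchor_identity: float = DEFAULT_MIN_ANCHOR_IDENTITY
    flank_bp_srad: int = FLANK_BP_SRAD
    flank_bp_simd: int = FLANK_BP_SIMD
    min_srad_bp: int = DEFAULT_MIN_SRAD_BP
    min_simd_bp: int = DEFAULT_MIN_SIMD_BP
    merge_bp: int = DEFAULT_MERGE_BP
    nahr_min_homology: int = DEFAULT_NAHR_MIN_HOMOLOGY


@dataclass
class DetectResult:
    calls: List[DeletionCall]
    skipped: List[Tuple[str, str]]  # (locus description, reason)


def _extract(genome: Dict[str, str], interval: GenomicInterval, flank_bp: int
             ) -> Tuple[str, GenomicInterval]:
    contig = genome[interval.seq_id]
    start = max(0, interval.start - flank_bp)
    end = min(len(contig), interval.end + flank_bp)
    return contig[start:end], GenomicInterval(interval.seq_id, start, end, "+")


def detect_events(
    derived_genome: Dict[str, str],
    ancestral_genome: Dict[str, str],
    derived_annotations: Sequence[RepeatFeature],
    ancestral_annotations: Sequence[RepeatFeature],
    params: Optional[DetectParams] = None,
    mode: str = "both",
) -> DetectResult:
    """Screen every derived-genome SVA locus for SRAD/SIMD events."""
    p = params or DetectParams()
    if mode not in ("srad", "simd", "both"):
        raise ValueError("mode must be srad, simd or both")
    index = GenomeKmerIndex(ancestral_genome, p.anchor_k)
    anc_svas = [f for f in ancestral_annotations if f.is_sva]
    calls: List[DeletionCall] = []
    skipped: List[Tuple[str, str]] = []

    for feat in derived_annotations:
        if not feat.is_sva:
            continue
        desc = f"{feat.interval.seq_id}:{feat.interval.start}-{feat.interval.end}"
        qseq, qiv = _extract(derived_genome, feat.interval, p.flank_bp_srad)
        # identity is checked on flank sequence only; a deletion may have
        # eaten into the flank, so clamp the window to what is left
        fb = min(p.flank_bp_srad,
                 max(100, feat.interval.start - qiv.start),
                 max(100, qiv.end - feat.interval.end))
        try:
            cand = anchor_ortholog(qseq, ancestral_genome, k=p.anchor_k,
                                   min_anchor_identity=p.min_anchor_identity,
                                   flank_bp=fb, index=index)
        except ValueError as exc:
            skipped.append((desc, f"anchor error: {exc}"))
            continue
        if cand is None:
            skipped.append((desc, "unmappable"))
            continue
        shared = any(f.interval.overlaps(cand) for f in anc_svas)

        if shared and mode in ("srad", "both"):
            tseq = ancestral_genome[cand.seq_id][cand.start:cand.end]
            pair = build_locus_pair(qiv, cand, qseq, tseq, p.align,
                                    locus_id=feat.interval.seq_id)
            call = call_srad(pair, list(derived_annotations), list(ancestral_annotations),
                             p.min_srad_bp, p.merge_bp, ancestral_seq=tseq)
            if call is not None:
                calls.append(call)
        elif not shared and mode in ("simd", "both"):
            qseq2, qiv2 = _extract(derived_genome, feat.interval, p.flank_bp_simd)
            s = feat.interval.start - qiv2.start
            e = feat.interval.end - qiv2.start
            masked = qseq2[:s] + qseq2[e:]
            try:
                cand2 = anchor_ortholog(masked, ancestral_genome, k=p.anchor_k,
                                        min_anchor_identity=p.min_anchor_identity,
                                        flank_bp=min(p.flank_bp_simd,
                                                     max(100, s),
                                                     max(100, len(qseq2) - e)),
                                        index=index)
            except ValueError as exc:
                skipped.append((desc, f"anchor error: {exc}"))
                continue
            if cand2 is None:
                skipped.append((desc, "unmappable"))
                continue
            tseq2 = ancestral_genome[cand2.seq_id][cand2.start:cand2.end]
            pair = build_locus_pair(qiv2, cand2, masked, tseq2, p.align,
                                    locus_id=feat.interval.seq_id)
            call, tsd = call_simd(pair, GenomicInterval(qiv2.seq_id, s, e),
                                  qseq2, p.min_simd_bp, p.merge_bp,
                                  ancestral_seq=tseq2)
            if call is not None:
                calls.append(call)
            elif tsd > 0:
                skipped.append((desc, f"clean insertion (TSD {tsd} bp)"))
    logger.info("detect: %d calls, %d loci skipped", len(calls), len(skipped))
    return DetectResult(calls, skipped)


def run_stages(
    derived_genome: Dict[str, str],
    ancestral_genome: Dict[str, str],
    derived_annotations: Sequence[RepeatFeature],
    ancestral_annotations: Sequence[RepeatFeature],
    ancestral_elements: Sequence[SVAElement] = (),
    params: Optional[DetectParams] = None,
    mode: str = "both",
) -> DetectResult:
    """Detect, classify mechanisms and annotate breakpoints in one pass."""
    p = params or DetectParams()
    result = detect_events(derived_genome, ancestral_genome, derived_annotations,
                           ancestral_annotations, p, mode)
    calls = classify_calls(result.calls, ancestral_genome,
                           list(ancestral_annotations), p.nahr_min_homology)
    calls = annotate_calls(calls, list(ancestral_annotations), list(ancestral_elements))
    return DetectResult(calls, result.skipped)
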