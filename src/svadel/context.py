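"""Flanking-sequence GC content and genic-context classification.

Deletions in GC-rich, gene-dense regions are more likely to affect genes, so
each event's flanks are compared against the genome-wide average GC fraction
(0.41 for human, supplied as a reference value, not recomputed) and each
deletion is classified as intergenic, intragenic or exonic against a set of
gene models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import GenomicInterval
from .io import GeneModel

DEFAULT_REFERENCE_GC = 0.41
DEFAULT_FLANK_BP = 10_000


@dataclass(frozen=True)
class GcResult:
    gc_fraction: float      # GC / non-N bases over both flanks combined; nan if undefined
    non_n_bases: int
    undefined: bool = False


def flank_gc(genome: Dict[str, str], locus: GenomicInterval,
             flank_bp: int = DEFAULT_FLANK_BP) -> GcResult:
    """GC fraction of the combined flanks (``flank_bp`` each side) of a locus.

    N bases are excluded from the denominator; contig-end clipping shrinks
    the flanks.  If both flanks are entirely N (or empty), the value is
    undefined.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    contig = genome[locus.seq_id]
    left = contig[max(0, locus.start - flank_bp):locus.start]
    right = contig[locus.end:locus.end + flank_bp]
    combined = (left + right).upper()
    non_n = sum(1 for b in combined if b != "N")
    if non_n == 0:
        return GcResult(float("nan"), 0, undefined=True)
    gc = sum(1 for b in combined if b in "GC")
    return GcResult(gc / non_n, non_n)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False
    reject_at_05: Optional[bool] = None


def gc_onesample_test(gc_values: Sequence[float], reference: float = DEFAULT_REFERENCE_GC,
                      alternative: str = "greater") -> TTestResult:
    """One-sample t-test of mean flank GC against the genome-wide reference.

    ``alternative`` is ``greater`` (default: is the flank GC *higher* than
    the reference?) or ``two_sided``.  With zero sample variance the t
    statistic is degenerate; the result is flagged and the exact decision
    (reject iff mean != reference) reported.
    """
    vals = np.asarray(list(gc_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two values")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    sd = vals.std(ddof=1)
    if sd == 0:
        mean = float(vals.mean())
        if mean == reference:
            p = 0.5 if alternative == "greater" else 1.0
            return TTestResult(0.0, p, degenerate=True, reject_at_05=False)
        sign = 1.0 if mean > reference else -1.0
        reject = mean > reference if alternative == "greater" else True
        return TTestResult(sign * float("inf"), 0.0 if reject else 1.0,
                           degenerate=True, reject_at_05=reject)
    alt = "greater" if alternative == "greater" else "two-sided"
    res = stats.ttest_1samp(vals, popmean=reference, alternative=alt)
    return TTestResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class GenicContext:
    label: str  # intergenic | intragenic | exonic
    exon_count: int = 0
    gene_names: Tuple[str, ...] = ()


def classify_genic_context(deletion: GenomicInterval,
                           gene_models: Sequence[GeneModel]) -> GenicContext:
    """Classify a deletion as exonic, intragenic or intergenic.

    Exonic if it overlaps at least one exon (exon count reported); otherwise
    intragenic if it overlaps any transcription unit; otherwise intergenic.
    Overlapping-gene ambiguity resolves toward exonic.
    """
    exon_hits = 0
    exonic_genes = []
    intragenic_genes = []
    for gene in gene_models:
        hits = sum(1 for exon in gene.exons if exon.overlaps(deletion))
        if hits:
            exon_hits += hits
            exonic_genes.append(gene.name)
        elif gene.interval.overlaps(deletion):
            intragenic_genes.append(gene.name)
    if exon_hits:
        return GenicContext("exonic", exon_hits, tuple(exonic_genes))
    if intragenic_genes:
        return GenicContext("intragenic", 0, tuple(intragenic_genes))
    return GenicContext("intergenic")
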