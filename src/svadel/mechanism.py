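"""Junction microhomology measurement and NHEJ/NAHR mechanism classification.

A deletion junction produced by end joining typically carries a short
identical word shared by both sides of the break (microhomology), which makes
the exact breakpoint placement ambiguous over a shift range.  Nonallelic
homologous recombination between two elements of the same repeat family
instead requires substantial homology at both breakpoints — here, the long
shared poly-A tails of two SVA elements.  The classifier separates the two
regimes with a configurable homology threshold and a same-family requirement
on the breakpoint annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core import DeletionCall, EventType, GenomicInterval, Mechanism, RepeatFeature

# NHEJ junctions observed in this class of events carry at most a few bases
# of microhomology while poly-A NAHR requires tens; 20 bp sits in the gap.
DEFAULT_NAHR_MIN_HOMOLOGY = 20


@dataclass(frozen=True)
class JunctionReport:
    """Microhomology at one deletion junction.

    ``left_ext_bp``/``right_ext_bp`` are the homology extents on either side
    of the nominal breakpoints; ``shift_range`` is the half-open interval of
    equivalent left-breakpoint placements, whose length equals the total
    microhomology.
    """

    left_ext_bp: int
    right_ext_bp: int
    shift_range: Tuple[int, int]
    mechanism: Optional[Mechanism] = None

    @property
    def microhomology_bp(self) -> int:
        return self.left_ext_bp + self.right_ext_bp

    def __post_init__(self) -> None:
        if self.shift_range[1] - self.shift_range[0] != self.left_ext_bp + self.right_ext_bp:
            raise ValueError("shift_range length != microhomology")


def _bases_equal(a: str, b: str) -> bool:
    a, b = a.upper(), b.upper()
    return a == b and a != "N"


def measure_microhomology(ancestral_seq: str, L: int, R: int) -> JunctionReport:
    """Measure exact junction homology for the deletion ``ancestral[L:R]``.

    The derived junction is ``ancestral[:L] + ancestral[R:]``.  The right
    extension is the longest k with ``seq[L:L+k] == seq[R:R+k]`` (k <= R-L);
    the left extension the longest j with ``seq[L-j:L] == seq[R-j:R]``
    (j <= L).  N never matches; matching is case-insensitive.
    """
    if not (0 <= L < R <= len(ancestral_seq)):
        raise ValueError(f"invalid breakpoints L={L}, R={R} for length {len(ancestral_seq)}")
    k = 0
    while L + k < R and R + k < len(ancestral_seq) \
            and _bases_equal(ancestral_seq[L + k], ancestral_seq[R + k]):
        k += 1
    j = 0
    while j < L and _bases_equal(ancestral_seq[L - j - 1], ancestral_seq[R - j - 1]):
        j += 1
    return JunctionReport(left_ext_bp=j, right_ext_bp=k, shift_range=(L - j, L + k))


def classify_mechanism(
    call: DeletionCall,
    junction: JunctionReport,
    ancestral_annotations: Sequence[RepeatFeature],
    nahr_min_homology: int = DEFAULT_NAHR_MIN_HOMOLOGY,
) -> Mechanism:
    """Classify an SRAD as NAHR or NHEJ.

    NAHR requires (a) junction homology >= ``nahr_min_homology`` and (b) both
    breakpoints inside annotated elements of the same repeat family (the two
    prerecombination elements); anything else is NHEJ.
    """
    if call.event_type != EventType.SRAD:
        raise ValueError("mechanism classification applies to SRAD calls only")
    if ancestral_annotations is None:
        raise ValueError("ancestral annotations are required")
    if junction.microhomology_bp < nahr_min_homology:
        return Mechanism.NHEJ
    left_fams = _covering_families(call.ancestral_deleted.seq_id,
                                   call.ancestral_deleted.start, ancestral_annotations)
    right_fams = _covering_families(call.ancestral_deleted.seq_id,
                                    call.ancestral_deleted.end, ancestral_annotations)
    if left_fams & right_fams:
        return Mechanism.NAHR
    return Mechanism.NHEJ


def _covering_families(seq_id: str, pos: int, features: Sequence[RepeatFeature]) -> set:
    return {f.repeat_class_family for f in features
            if f.interval.contains_point(pos, seq_id)}


def classify_mechanism_from_labels(
    microhomology_bp: int,
    left_label: str,
    right_label: str,
    nahr_min_homology: int = DEFAULT_NAHR_MIN_HOMOLOGY,
) -> Mechanism:
    """Label-based variant used for tabulated breakpoint annotations.

    Labels beginning with ``SVA`` denote the SVA family; ``Unique`` denotes
    unannotated sequence (no family).  NAHR requires both breakpoints in the
    same family plus the homology threshold, exactly as the sequence-based
    classifier.
    """

    def family(label: str) -> Optional[str]:
        label = label.strip()
        if label.lower().startswith("unique"):
            return None
        if label.startswith("SVA"):
            return "SVA"
        return label
    if microhomology_bp < nahr_min_homology:
        return Mechanism.NHEJ
    lf, rf = family(left_label), family(right_label)
    if lf is not None and lf == rf:
        return Mechanism.NAHR
    return Mechanism.NHEJ


def classify_calls(
    calls: Sequence[DeletionCall],
    ancestral_genome: Dict[str, str],
    ancestral_annotations: Sequence[RepeatFeature],
    nahr_min_homology: int = DEFAULT_NAHR_MIN_HOMOLOGY,
) -> List[DeletionCall]:
    """Measure microhomology and set the mechanism for every SRAD call.

    Breakpoints are re-normalized to the leftmost placement of the junction's
    shift range; SIMD calls pass through unchanged.
    """
    out: List[DeletionCall] = []
    for call in calls:
        if call.event_type != EventType.SRAD:
            out.append(call)
            continue
        seq = ancestral_genome[call.ancestral_deleted.seq_id]
        junction = measure_microhomology(seq, call.ancestral_deleted.start,
                                         call.ancestral_deleted.end)
        mech = classify_mechanism(call, junction, ancestral_annotations, nahr_min_homology)
        shift_left = call.ancestral_deleted.start - junction.shift_range[0]
        deleted = call.ancestral_deleted.shifted(-shift_left)
        out.append(dataclasses.replace(
            call,
            ancestral_deleted=deleted,
            derived_junction=call.derived_junction.shifted(-min(shift_left,
                                                                call.derived_junction.start)),
            microhomology_bp=junction.microhomology_bp,
            mechanism=mech,
        ))
    return out


def render_junction_alignment(ancestral_seq: str, L: int, R: int,
                              context_bp: int = 30) -> str:
    """Fixed-width three-row text view of a deletion junction.

    Row 1 is the derived chimera around the junction, rows 2 and 3 the
    ancestral sequence around the left and right breakpoints; dots mark bases
    identical to the chimera row and the microhomology span is bracketed.
    """
    junction = measure_microhomology(ancestral_seq, L, R)
    mh = junction.microhomology_bp
    if context_bp < mh:
        raise ValueError("context_bp must be >= the microhomology length")
    ctx = context_bp
    lo = max(0, L - ctx)
    derived_row = ancestral_seq[lo:L] + ancestral_seq[R:R + ctx]
    left_row = ancestral_seq[lo:min(L + ctx, R)]
    right_row = ancestral_seq[max(R - (L - lo), 0):R + ctx]
    width = (L - lo) + ctx

    def dotted(row: str, offset: int) -> str:
        cells = []
        for i in range(width):
            j = i - offset
            if 0 <= j < len(row):
                cells.append("." if _bases_equal(row[j], derived_row[i])
                             and row[j].upper() == derived_row[i].upper() else row[j])
            else:
                cells.append(" ")
        return "".join(cells)

    mark = [" "] * width
    jcol = L - lo
    for i in range(jcol - junction.left_ext_bp, jcol + junction.right_ext_bp):
        if 0 <= i < width:
            mark[i] = "^"
    label_w = 10
    lines = [
        f"{'derived':<{label_w}}{derived_row:<{width}}",
        f"{'anc.left':<{label_w}}{dotted(left_row, 0)}",
        f"{'anc.right':<{label_w}}{dotted(right_row, (L - lo) - (R - max(R - (L - lo), 0)))}",
    ]
    if mh > 0:
        lines.append(f"{'':<{label_w}}{''.join(mark)}  microhomology {mh} bp")
    return "\n".join(line.rstrip() for line in lines) + "\n"
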