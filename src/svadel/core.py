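"""Domain types and sequence/coordinate primitives shared by all pipeline stages.

All in-memory coordinates are 0-based, half-open ``[start, end)``.  External
formats that print 1-based inclusive positions (RepeatMasker ``.out``, the
report tables) are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

__all__ = [
    "Strand",
    "GenomicInterval",
    "SvaSegment",
    "SVAElement",
    "RepeatFeature",
    "BreakpointKind",
    "BreakpointAnnotation",
    "EventType",
    "Mechanism",
    "DeletionCall",
    "SVA_SUBFAMILIES",
    "reverse_complement",
    "convert_coordinates",
]


# ---------------------------------------------------------------------------
# intervals

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded).  Intervals on different
    sequences never overlap or contain one another.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in {self}")
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def is_empty(self) -> bool:
        return self.end == self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        if self.seq_id != other.seq_id:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        if self.seq_id != other.seq_id:
            return False
        return self.start <= other.start and other.end <= self.end

    def contains_point(self, pos: int, seq_id: Optional[str] = None) -> bool:
        if seq_id is not None and seq_id != self.seq_id:
            return False
        return self.start <= pos < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Number of bases strictly between two intervals on the same sequence.

        Returns ``None`` for intervals on different sequences; 0 when they
        overlap or abut.
        """
        if self.seq_id != other.seq_id:
            return None
        if self.overlaps(other):
            return 0
        return max(other.start - self.end, self.start - other.end, 0)

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


# ---------------------------------------------------------------------------
# SVA substructure

SVA_SUBFAMILIES = ("SVA_A", "SVA_B", "SVA_C", "SVA_D", "SVA_E", "SVA_F", "SVA2")


class SvaSegment(enum.IntEnum):
    """Substructure blocks of a composite SVA element.

    The integer values are the breakpoint-localization codes used in the
    results tables: 1 Alu-like, 2 VNTR, 3 SINE-R, 4 poly-A tail, 5 hexamer
    (CCCTCT)n repeats, 6 SVA2-specific sequence.
    """

    ALU_LIKE = 1
    VNTR = 2
    SINE_R = 3
    POLY_A = 4
    HEXAMER = 5
    SVA2_SPECIFIC = 6


@dataclass(frozen=True)
class SVAElement:
    """An SVA element with its ordered substructure annotation.

    ``segments`` is an ordered list of ``(SvaSegment, GenomicInterval)``
    pairs; segment intervals must be sorted, non-overlapping and contained in
    ``interval``.
    """

    interval: GenomicInterval
    subfamily: str
    segments: Tuple[Tuple[SvaSegment, GenomicInterval], ...] = ()

    def __post_init__(self) -> None:
        if self.subfamily not in SVA_SUBFAMILIES:
            raise ValueError(f"unknown SVA subfamily {self.subfamily!r}")
        object.__setattr__(self, "segments", tuple(
            (SvaSegment(code), iv) for code, iv in self.segments))
        prev_end = None
        for _, iv in self.segments:
            if not self.interval.contains(iv):
                raise ValueError(f"segment {iv} outside element {self.interval}")
            if prev_end is not None and iv.start < prev_end:
                raise ValueError("segments overlap or are unsorted")
            prev_end = iv.end

    def segment_at(self, pos: int) -> Optional[SvaSegment]:
        """Segment code containing ``pos`` (half-open), or None."""
        for code, iv in self.segments:
            if iv.contains_point(pos, self.interval.seq_id):
                return code
        return None


@dataclass(frozen=True)
class RepeatFeature:
    """One repeat annotation row (RepeatMasker-style)."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class_family: str
    divergence_pct: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError(f"divergence {self.divergence_pct} outside [0, 100]")
        if self.interval.length() <= 0:
            raise ValueError("repeat feature must have positive length")

    @property
    def is_sva(self) -> bool:
        return (self.repeat_class_family.split("/")[-1] == "SVA"
                or self.repeat_name.startswith("SVA"))


# ---------------------------------------------------------------------------
# deletion calls

class BreakpointKind(str, enum.Enum):
    SVA_SEGMENT = "SVA_SEGMENT"
    REPEAT = "REPEAT"
    UNIQUE = "UNIQUE"


@dataclass(frozen=True)
class BreakpointAnnotation:
    kind: BreakpointKind
    sva_segment_code: Optional[SvaSegment] = None
    repeat_name: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.kind == BreakpointKind.SVA_SEGMENT) != (self.sva_segment_code is not None):
            raise ValueError("sva_segment_code present iff kind == SVA_SEGMENT")
        if (self.kind == BreakpointKind.REPEAT) != (self.repeat_name is not None):
            raise ValueError("repeat_name present iff kind == REPEAT")

    def label(self) -> str:
        if self.kind == BreakpointKind.UNIQUE:
            return "Unique"
        if self.kind == BreakpointKind.REPEAT:
            return self.repeat_name  # type: ignore[return-value]
        return f"SVA({int(self.sva_segment_code)})"  # type: ignore[arg-type]


class EventType(str, enum.Enum):
    SRAD = "SRAD"  # recombination-associated deletion (NHEJ or NAHR)
    SIMD = "SIMD"  # insertion-mediated deletion


class Mechanism(str, enum.Enum):
    NHEJ = "NHEJ"
    NAHR = "NAHR"
    NA = "NA"


@dataclass(frozen=True)
class DeletionCall:
    """One called deletion event.

    For an SRAD, ``derived_junction`` is the zero-length junction point in the
    derived genome; for a SIMD it is the interval of the inserted SVA.
    ``ancestral_deleted`` is the deleted interval in ancestral coordinates and
    ``deletion_size`` always equals its length.  ``microhomology_bp`` is
    defined for SRADs only (None before the mechanism stage and for SIMDs).
    """

    event_type: EventType
    locus_id: str
    derived_junction: GenomicInterval
    ancestral_deleted: GenomicInterval
    deletion_size: int
    microhomology_bp: Optional[int] = None
    mechanism: Mechanism = Mechanism.NA
    left_breakpoint_annotation: Optional[BreakpointAnnotation] = None
    right_breakpoint_annotation: Optional[BreakpointAnnotation] = None
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.deletion_size <= 0:
            raise ValueError("deletion_size must be positive")
        if self.deletion_size != self.ancestral_deleted.length():
            raise ValueError("deletion_size != ancestral_deleted length")
        if self.event_type == EventType.SIMD:
            if self.mechanism != Mechanism.NA:
                raise ValueError("SIMD events carry mechanism NA")
            if self.microhomology_bp is not None:
                raise ValueError("SIMD events carry no microhomology")
        if self.microhomology_bp is not None and self.microhomology_bp < 0:
            raise ValueError("microhomology_bp must be non-negative")


# ---------------------------------------------------------------------------
# sequence primitives

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)
_IUPAC_RE = re.compile(r"[^ACGTUMRWSYKVHDBNacgtumrwsykvhdbn]")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string, preserving case.

    Raises ``ValueError`` naming the position of the first non-IUPAC
    character.
    """
    m = _IUPAC_RE.search(seq)
    if m:
        raise ValueError(
            f"non-IUPAC character {m.group()!r} at position {m.start()}")
    return seq.translate(_COMPLEMENT)[::-1]


def convert_coordinates(pos: int, from_convention: str, role: str) -> int:
    """Convert a single coordinate between 1-based inclusive and 0-based half-open.

    ``role`` is "start" or "end"; conversion is lossless and preserves
    interval length.
    """
    if role not in ("start", "end"):
        raise ValueError(f"role must be 'start' or 'end', got {role!r}")
    if from_convention == "one_based_inclusive":
        if pos < 1:
            raise ValueError(f"1-based coordinate must be >= 1, got {pos}")
        return pos - 1 if role == "start" else pos
    if from_convention == "zero_based_half_open":
        if pos < 0:
            raise ValueError(f"0-based coordinate must be >= 0, got {pos}")
        return pos + 1 if role == "start" else pos
    raise ValueError(f"unknown convention {from_convention!r}")
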