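"""Synthetic ancestral/derived locus pairs with planted SVA-associated deletions.

Each locus is an independent contig carrying a composite SVA element between
long unique flanks.  Four scenarios are planted:

* ``NHEJ_SRAD`` — a deletion spanning one SVA boundary (part of the element
  plus adjacent flank) with an engineered junction microhomology of an exact,
  known length;
* ``NAHR_SRAD`` — two same-subfamily SVAs recombined through their poly-A
  tails into a single chimera, deleting the 3' part of the first element, the
  intervening sequence and the 5' part of the second;
* ``SIMD`` — an SVA insertion that replaces target sequence without leaving a
  target-site duplication;
* ``NEUTRAL`` — a shared SVA with no event.

The generator guarantees the planted microhomology is the unique maximal
junction homology (boundary bases are rejection-fixed), so recovering it is a
well-posed test.  Event footprints stay >= 200 bp away from contig ends.
Between-genome divergence is modelled as substitutions only, applied to the
derived sequence outside a small protected window around each junction.

SVA substructure blocks are synthetic per-subfamily template sequences (fixed
by an internal seed), not real repeat consensi; they carry the correct block
architecture — (CCCTCT)n hexamer, Alu-like, 40-bp-unit VNTR, SINE-R, poly-A —
which is all the downstream coordinate arithmetic depends on.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, RepeatFeature, SVAElement, SvaSegment, SVA_SUBFAMILIES
from .io import write_fasta, write_repeatmasker_out, write_sva_track

SCENARIOS = ("NHEJ_SRAD", "NAHR_SRAD", "SIMD", "NEUTRAL")

EDGE_MARGIN = 200  # planted events never touch the outer margin of a contig

_ALU_LIKE_LEN = 330
_SINE_R_LEN = 490
_VNTR_UNIT_LEN = 40
_HEXAMER = "CCCTCT"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_loci: int = 50
    scenario_mix: Dict[str, float] = field(default_factory=lambda: {
        "NHEJ_SRAD": 0.23, "NAHR_SRAD": 0.02, "SIMD": 0.25, "NEUTRAL": 0.50})
    flank_bp: int = 2000
    srad_size_range: Tuple[int, int] = (113, 4980)
    simd_size_range: Tuple[int, int] = (14, 8741)
    microhomology_range: Tuple[int, int] = (0, 7)
    nahr_homology_bp: int = 36
    background_gc: float = 0.425
    substitution_rate: float = 0.012

    def __post_init__(self) -> None:
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario_mix sums to {total}, expected 1")
        for s in self.scenario_mix:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        if self.flank_bp < 2 * EDGE_MARGIN:
            raise ValueError("flank_bp too small for edge margins")
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc outside [0,1]")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate outside [0,1]")


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth for one planted locus."""

    locus_id: str
    scenario: str
    ancestral_deleted: Optional[GenomicInterval]
    deletion_size: int
    microhomology_bp: Optional[int]
    sva_subfamily: str
    breakpoint_segment_codes: Tuple[Optional[SvaSegment], Optional[SvaSegment]]
    derived_insertion: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.scenario == "NEUTRAL" and self.deletion_size != 0:
            raise ValueError("NEUTRAL locus with nonzero deletion")


@dataclass
class SimulatedLocus:
    locus_id: str
    ancestral_seq: str
    derived_seq: str
    ancestral_elements: List[SVAElement]
    derived_elements: List[SVAElement]
    truth: LocusTruth


@dataclass
class SimulatedBatch:
    config: SimulationConfig
    loci: List[SimulatedLocus]

    @property
    def ancestral_genome(self) -> Dict[str, str]:
        return {l.locus_id: l.ancestral_seq for l in self.loci}

    @property
    def derived_genome(self) -> Dict[str, str]:
        return {l.locus_id: l.derived_seq for l in self.loci}

    def elements(self, side: str) -> List[SVAElement]:
        attr = "ancestral_elements" if side == "ancestral" else "derived_elements"
        return [el for l in self.loci for el in getattr(l, attr)]

    def repeat_features(self, side: str) -> List[RepeatFeature]:
        return [
            RepeatFeature(el.interval, el.subfamily, "Retroposon/SVA", 2.0)
            for el in self.elements(side)
        ]

    @property
    def truths(self) -> List[LocusTruth]:
        return [l.truth for l in self.loci]


# ---------------------------------------------------------------------------
# SVA sequence construction

@functools.lru_cache(maxsize=None)
def _subfamily_blocks(subfamily: str) -> Dict[str, str]:
    """Fixed synthetic template blocks, distinct per subfamily."""
    if subfamily not in SVA_SUBFAMILIES:
        raise ValueError(f"unknown SVA subfamily {subfamily!r}")
    rng = np.random.default_rng([20120520, SVA_SUBFAMILIES.index(subfamily)])
    bases = np.array(list("ACGT"))

    def block(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    return {
        "alu_like": block(_ALU_LIKE_LEN),
        "vntr_unit": block(_VNTR_UNIT_LEN),
        "sine_r": block(_SINE_R_LEN),
    }


def build_sva_sequence(
    subfamily: str,
    vntr_copies: int,
    rng: np.random.Generator,
    poly_a_len: Optional[int] = None,
    hexamer_copies: Optional[int] = None,
) -> Tuple[str, List[Tuple[SvaSegment, Tuple[int, int]]]]:
    """Assemble an SVA sequence; returns (sequence, [(code, (start, end)), ...]).

    Block order is hexamer, Alu-like (SVA2-specific block for SVA2), VNTR,
    SINE-R, poly-A; segments are contiguous and cover the whole element.
    """
    if vntr_copies < 1:
        raise ValueError("vntr_copies must be >= 1")
    blocks = _subfamily_blocks(subfamily)
    if hexamer_copies is None:
        hexamer_copies = int(rng.integers(3, 9))
    if poly_a_len is None:
        poly_a_len = int(rng.integers(16, 41))
    body_code = SvaSegment.SVA2_SPECIFIC if subfamily == "SVA2" else SvaSegment.ALU_LIKE
    parts = [
        (SvaSegment.HEXAMER, _HEXAMER * hexamer_copies),
        (body_code, blocks["alu_like"]),
        (SvaSegment.VNTR, blocks["vntr_unit"] * vntr_copies),
        (SvaSegment.SINE_R, blocks["sine_r"]),
        (SvaSegment.POLY_A, "A" * poly_a_len),
    ]
    seq = ""
    segments = []
    for code, part in parts:
        segments.append((code, (len(seq), len(seq) + len(part))))
        seq += part
    return seq, segments


def _element_at(locus_id: str, offset: int, subfamily: str,
                segments: Sequence[Tuple[SvaSegment, Tuple[int, int]]],
                clip: Optional[Tuple[int, int]] = None) -> Optional[SVAElement]:
    """Place an element (built at local coordinates) onto a contig.

    ``clip`` restricts to a sub-interval of the element in local coordinates
    (used for post-deletion remnants); returns None if nothing remains.
    """
    segs = []
    for code, (s, e) in segments:
        if clip is not None:
            s, e = max(s, clip[0]), min(e, clip[1])
            if s >= e:
                continue
        segs.append((code, GenomicInterval(locus_id, offset + s, offset + e, "+")))
    if not segs:
        return None
    iv = GenomicInterval(locus_id, segs[0][1].start, segs[-1][1].end, "+")
    return SVAElement(iv, subfamily, tuple(segs))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _pick_other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in {a.upper() for a in avoid}]
    return choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# planting operations

def plant_nhej_srad(
    locus: str,
    sva: SVAElement,
    deletion_size: int,
    microhomology_bp: int,
    rng: np.random.Generator,
    boundary: str = "right",
) -> Tuple[str, str, LocusTruth]:
    """Plant an NHEJ deletion spanning one SVA boundary.

    Returns (ancestral, derived, truth).  The ancestral sequence is the input
    locus with the junction engineered so that the maximal junction homology
    is exactly ``microhomology_bp``; the derived sequence has ``[L, R)``
    excised.
    """
    if microhomology_bp >= deletion_size:
        raise ValueError("microhomology must be shorter than the deletion")
    seq = list(locus)
    m = microhomology_bp
    sva_iv = sva.interval
    min_over = 20  # deletion must take at least this much of both element and flank
    in_sva_max = min(deletion_size - min_over, sva_iv.length() - min_over)
    if boundary == "right":
        in_sva_min = max(min_over,
                         sva_iv.end + deletion_size - (len(seq) - EDGE_MARGIN))
        if in_sva_max < in_sva_min:
            raise ValueError("deletion cannot span the SVA boundary at this size")
        in_sva = int(rng.integers(in_sva_min, in_sva_max + 1))
        L = sva_iv.end - in_sva
        R = L + deletion_size
    elif boundary == "left":
        in_sva_min = max(min_over, EDGE_MARGIN + deletion_size - sva_iv.start)
        if in_sva_max < in_sva_min:
            raise ValueError("deletion cannot span the SVA boundary at this size")
        in_sva = int(rng.integers(in_sva_min, in_sva_max + 1))
        R = sva_iv.start + in_sva
        L = R - deletion_size
    else:
        raise ValueError("boundary must be 'left' or 'right'")
    if L < EDGE_MARGIN or R > len(seq) - EDGE_MARGIN:
        raise ValueError("deletion exceeds locus bounds (with edge margin)")

    # engineer the junction: identical m-word on both sides, mismatching
    # boundary bases so the homology cannot extend further
    seq[R:R + m] = seq[L:L + m]
    if seq[L + m].upper() == seq[R + m].upper():
        seq[R + m] = _pick_other_base(rng, seq[L + m])
    if seq[L - 1].upper() == seq[R - 1].upper():
        seq[R - 1] = _pick_other_base(rng, seq[L - 1])
    ancestral = "".join(seq)
    derived = ancestral[:L] + ancestral[R:]

    left_code = sva.segment_at(L)
    right_code = sva.segment_at(R)
    truth = LocusTruth(
        locus_id=sva_iv.seq_id,
        scenario="NHEJ_SRAD",
        ancestral_deleted=GenomicInterval(sva_iv.seq_id, L, R),
        deletion_size=deletion_size,
        microhomology_bp=m,
        sva_subfamily=sva.subfamily,
        breakpoint_segment_codes=(left_code, right_code),
    )
    return ancestral, derived, truth


def plant_nahr_srad(
    locus_id: str,
    subfamily: str,
    flank_bp: int,
    intervening_bp: int,
    nahr_homology_bp: int,
    background_gc: float,
    rng: np.random.Generator,
) -> Tuple[str, str, LocusTruth, List[SVAElement], List[SVAElement]]:
    """Build and recombine two same-subfamily SVAs through their poly-A tails.

    The crossover joins the 5' part of the first element (through its poly-A)
    to the retained poly-A of the second; the deletion removes the first
    element's poly-A, the intervening sequence and the second element's body.
    Junction homology equals the (exact) shared poly-A length.
    """
    h = nahr_homology_bp
    if h < 5:
        raise ValueError("poly-A homology too short")
    seq1, segs1 = build_sva_sequence(subfamily, int(rng.integers(4, 10)), rng, poly_a_len=h)
    seq2, segs2 = build_sva_sequence(subfamily, int(rng.integers(4, 10)), rng, poly_a_len=h)
    flank_l = _random_seq(rng, flank_bp, background_gc)
    flank_r = _random_seq(rng, flank_bp, background_gc)
    intervening = _random_seq(rng, intervening_bp, background_gc)

    sva1_off = len(flank_l)
    sva2_off = sva1_off + len(seq1) + len(intervening)
    seq = list(flank_l + seq1 + intervening + seq2 + flank_r)

    L = sva1_off + len(seq1) - h       # poly-A start of element 1
    R = sva2_off + len(seq2) - h       # poly-A start of element 2
    # stop the homology at exactly h on both sides
    if seq[L - 1].upper() == seq[R - 1].upper():
        seq[R - 1] = _pick_other_base(rng, seq[L - 1])
    if seq[L + h].upper() in ("A", seq[R + h].upper()):
        seq[L + h] = _pick_other_base(rng, "A", seq[R + h])
    if seq[R + h].upper() == "A":
        seq[R + h] = _pick_other_base(rng, "A", seq[L + h])
    ancestral = "".join(seq)
    derived = ancestral[:L] + ancestral[R:]

    anc_elements = [
        _element_at(locus_id, sva1_off, subfamily, segs1),
        _element_at(locus_id, sva2_off, subfamily, segs2),
    ]
    # the chimera is one maximal element: 5' of element 1 plus a poly-A tail
    derived_elements = [_element_at(locus_id, sva1_off, subfamily, segs1)]

    truth = LocusTruth(
        locus_id=locus_id,
        scenario="NAHR_SRAD",
        ancestral_deleted=GenomicInterval(locus_id, L, R),
        deletion_size=R - L,
        microhomology_bp=h,
        sva_subfamily=subfamily,
        breakpoint_segment_codes=(SvaSegment.POLY_A, SvaSegment.POLY_A),
    )
    return ancestral, derived, truth, [e for e in anc_elements if e], \
        [e for e in derived_elements if e]


def plant_simd(
    locus: str,
    sva_seq: str,
    target_deletion_size: int,
    insertion_point: int,
    rng: np.random.Generator,
) -> Tuple[str, str, LocusTruth]:
    """Replace ``[L, L+d)`` of the locus with an SVA, with no target-site duplication."""
    d = target_deletion_size
    if d < 1:
        raise ValueError("target_deletion_size must be >= 1")
    L = insertion_point
    if L < EDGE_MARGIN or L + d > len(locus) - EDGE_MARGIN:
        raise ValueError("deletion out of bounds (with edge margin)")
    seq = list(locus)
    # avoid an accidental >=5 bp duplication flanking the insertion, which
    # would mimic a clean TPRT target-site duplication
    from .calling import detect_tsd  # local import to avoid a cycle at load

    for _ in range(50):
        derived = "".join(seq[:L]) + sva_seq + "".join(seq[L + d:])
        ins_iv = GenomicInterval("", L, L + len(sva_seq))
        if detect_tsd(derived, ins_iv, 20) == 0:
            break
        seq[L + d + 4] = _pick_other_base(rng, seq[L + d + 4])
    ancestral = "".join(seq)
    derived = ancestral[:L] + sva_seq + ancestral[L + d:]
    return ancestral, derived, LocusTruth(
        locus_id="",
        scenario="SIMD",
        ancestral_deleted=GenomicInterval("", L, L + d),
        deletion_size=d,
        microhomology_bp=None,
        sva_subfamily="",
        breakpoint_segment_codes=(None, None),
    )


# ---------------------------------------------------------------------------
# per-locus assembly

_SRAD_SUBFAMILY = (["SVA_A", "SVA_B", "SVA_C", "SVA_D", "SVA2"],
                   [0.18, 0.24, 0.24, 0.24, 0.10])
_SIMD_SUBFAMILY = (["SVA_B", "SVA_C", "SVA_D", "SVA_E"],
                   [0.08, 0.14, 0.70, 0.08])


def _apply_substitutions(derived: str, rate: float, protected: List[Tuple[int, int]],
                         rng: np.random.Generator) -> str:
    if rate <= 0:
        return derived
    n = len(derived)
    k = rng.binomial(n, rate)
    if k == 0:
        return derived
    positions = rng.choice(n, size=k, replace=False)
    seq = list(derived)
    for pos in sorted(int(p) for p in positions):
        if any(s <= pos < e for s, e in protected):
            continue
        seq[pos] = _pick_other_base(rng, seq[pos])
    return "".join(seq)


def _simulate_locus(locus_id: str, scenario: str, config: SimulationConfig,
                    rng: np.random.Generator) -> SimulatedLocus:
    gc = config.background_gc
    flank = config.flank_bp

    if scenario == "NAHR_SRAD":
        intervening = int(rng.integers(50, 800))
        anc, der, truth, anc_els, der_els = plant_nahr_srad(
            locus_id, str(rng.choice(["SVA_A", "SVA_B", "SVA_C"])), flank,
            intervening, config.nahr_homology_bp, gc, rng)
        protected = [(truth.ancestral_deleted.start - 20,
                      truth.ancestral_deleted.start + config.nahr_homology_bp + 20)]
        der = _apply_substitutions(der, config.substitution_rate, protected, rng)
        return SimulatedLocus(locus_id, anc, der, anc_els, der_els, truth)

    subfam_pool = _SRAD_SUBFAMILY if scenario in ("NHEJ_SRAD", "NEUTRAL") else _SIMD_SUBFAMILY
    subfamily = str(rng.choice(subfam_pool[0], p=subfam_pool[1]))
    sva_seq, segments = build_sva_sequence(subfamily, int(rng.integers(4, 16)), rng)

    if scenario == "SIMD":
        lo, hi = config.simd_size_range
        d = int(rng.integers(lo, hi + 1))
        locus = _random_seq(rng, 2 * flank + d, gc)
        anc, der, truth0 = plant_simd(locus, sva_seq, d, flank, rng)
        ins_iv = GenomicInterval(locus_id, flank, flank + len(sva_seq), "+")
        truth = LocusTruth(locus_id, "SIMD",
                           GenomicInterval(locus_id, flank, flank + d),
                           d, None, subfamily, (None, None), derived_insertion=ins_iv)
        der_el = _element_at(locus_id, flank, subfamily, segments)
        protected = [(flank - 20, flank + 20),
                     (flank + len(sva_seq) - 20, flank + len(sva_seq) + 20)]
        der = _apply_substitutions(der, config.substitution_rate, protected, rng)
        return SimulatedLocus(locus_id, anc, der, [], [der_el] if der_el else [], truth)

    # shared-element scenarios
    locus = (_random_seq(rng, flank, gc) + sva_seq + _random_seq(rng, flank, gc))
    sva = _element_at(locus_id, flank, subfamily, segments)
    assert sva is not None

    if scenario == "NEUTRAL":
        truth = LocusTruth(locus_id, "NEUTRAL", None, 0, None, subfamily, (None, None))
        der = _apply_substitutions(locus, config.substitution_rate, [], rng)
        return SimulatedLocus(locus_id, locus, der, [sva], [sva], truth)

    # NHEJ_SRAD
    lo, hi = config.srad_size_range
    boundary = "right" if rng.random() < 0.5 else "left"
    feasible_hi = min(hi, sva.interval.length() - 20 + flank - EDGE_MARGIN - 20)
    size = int(rng.integers(lo, max(lo, feasible_hi) + 1))
    m = int(rng.integers(config.microhomology_range[0], config.microhomology_range[1] + 1))
    anc, der, truth = plant_nhej_srad(locus, sva, size, m, rng, boundary)
    L = truth.ancestral_deleted.start
    if boundary == "right":
        remnant = _element_at(locus_id, flank, subfamily, segments, clip=(0, L - flank))
        der_els = [remnant] if remnant else []
    else:
        # ancestral [R, sva_end) survives; in derived it begins at L
        R = truth.ancestral_deleted.end
        remnant = _element_at(locus_id, L - (R - flank), subfamily, segments,
                              clip=(R - flank, len(sva_seq)))
        der_els = [remnant] if remnant else []
    protected = [(L - 20, L + m + 20)]
    der = _apply_substitutions(der, config.substitution_rate, protected, rng)
    return SimulatedLocus(locus_id, anc, der, [sva], der_els, truth)


# ---------------------------------------------------------------------------
# batch driver

def simulate_batch(config: SimulationConfig) -> SimulatedBatch:
    """Generate ``n_loci`` independent loci, deterministic under ``config.seed``."""
    rng = np.random.default_rng([config.seed, 0])
    names = [s for s in SCENARIOS if config.scenario_mix.get(s, 0) > 0]
    probs = np.array([config.scenario_mix[s] for s in names])
    probs = probs / probs.sum()
    scenarios = [names[i] for i in rng.choice(len(names), size=config.n_loci, p=probs)]
    loci = []
    for i, scenario in enumerate(scenarios):
        locus_rng = np.random.default_rng([config.seed, i + 1])
        locus_id = f"locus{i + 1:04d}"
        loci.append(_simulate_locus(locus_id, scenario, config, locus_rng))
    return SimulatedBatch(config, loci)


def write_batch(batch: SimulatedBatch, outdir) -> Dict[str, Path]:
    """Write FASTA x2, RepeatMasker .out x2, SVA substructure tracks and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ancestral_fasta": outdir / "ancestral.fa",
        "derived_fasta": outdir / "derived.fa",
        "ancestral_rm": outdir / "ancestral.out",
        "derived_rm": outdir / "derived.out",
        "ancestral_sva": outdir / "ancestral_sva.bed",
        "derived_sva": outdir / "derived_sva.bed",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(batch.ancestral_genome, paths["ancestral_fasta"])
    write_fasta(batch.derived_genome, paths["derived_fasta"])
    write_repeatmasker_out(batch.repeat_features("ancestral"), paths["ancestral_rm"])
    write_repeatmasker_out(batch.repeat_features("derived"), paths["derived_rm"])
    write_sva_track(batch.elements("ancestral"), paths["ancestral_sva"])
    write_sva_track(batch.elements("derived"), paths["derived_sva"])
    write_truth_tsv(batch.truths, paths["truth"])
    return paths


def write_truth_tsv(truths: Sequence[LocusTruth], path) -> None:
    rows = []
    for t in truths:
        rows.append({
            "locus_id": t.locus_id,
            "scenario": t.scenario,
            "del_start": "" if t.ancestral_deleted is None else t.ancestral_deleted.start,
            "del_end": "" if t.ancestral_deleted is None else t.ancestral_deleted.end,
            "deletion_size": t.deletion_size,
            "microhomology_bp": "" if t.microhomology_bp is None else t.microhomology_bp,
            "sva_subfamily": t.sva_subfamily,
            "left_code": "" if t.breakpoint_segment_codes[0] is None
                         else int(t.breakpoint_segment_codes[0]),
            "right_code": "" if t.breakpoint_segment_codes[1] is None
                          else int(t.breakpoint_segment_codes[1]),
            "ins_start": "" if t.derived_insertion is None else t.derived_insertion.start,
            "ins_end": "" if t.derived_insertion is None else t.derived_insertion.end,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> List[LocusTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    truths = []
    for _, r in df.iterrows():
        deleted = None
        if r["del_start"] != "":
            deleted = GenomicInterval(r["locus_id"], int(r["del_start"]), int(r["del_end"]))
        ins = None
        if r["ins_start"] != "":
            ins = GenomicInterval(r["locus_id"], int(r["ins_start"]), int(r["ins_end"]), "+")
        truths.append(LocusTruth(
            r["locus_id"], r["scenario"], deleted, int(r["deletion_size"]),
            None if r["microhomology_bp"] == "" else int(r["microhomology_bp"]),
            r["sva_subfamily"],
            (None if r["left_code"] == "" else SvaSegment(int(r["left_code"])),
             None if r["right_code"] == "" else SvaSegment(int(r["right_code"]))),
            ins,
        ))
    return truths
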