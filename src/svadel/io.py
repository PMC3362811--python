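"""Readers and writers for the formats the pipeline exchanges.

FASTA, RepeatMasker ``.out``, BED6, GFF3 gene models, an SVA substructure
track (BED-like), the results TSV, and the packaged result-table fixtures.
Every reader rejects malformed records instead of skipping them, and 1-based
inclusive coordinates exist only inside this module.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .core import (
    BreakpointAnnotation,
    BreakpointKind,
    DeletionCall,
    EventType,
    GenomicInterval,
    Mechanism,
    RepeatFeature,
    SVAElement,
    SvaSegment,
    convert_coordinates,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a (possibly multi-record) FASTA file into ``{id: sequence}``.

    Ids are the first whitespace-delimited token; case is preserved.
    Duplicate ids and empty records are errors.
    """
    records: Dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            seq_id = title.split()[0] if title.split() else ""
            if not seq_id:
                raise ValueError(f"{path}: record with empty id")
            if seq_id in records:
                raise ValueError(f"{path}: duplicate sequence id {seq_id!r}")
            if not seq:
                raise ValueError(f"{path}: empty record {seq_id!r}")
            records[seq_id] = seq
    logger.info("read %d FASTA records from %s", len(records), path)
    return records


def write_fasta(records: Dict[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    logger.info("wrote %d FASTA records to %s", len(records), path)


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = """\
   SW   perc perc perc  query     position in query           matching repeat       position in repeat
score   div. del. ins.  sequence  begin  end        (left)   repeat equiv.class  begin  end    (left)  ID

"""


def read_repeatmasker_out(path: PathLike) -> List[RepeatFeature]:
    """Parse a standard RepeatMasker ``.out`` annotation table.

    Coordinates are converted to 0-based half-open; strand ``C`` maps to
    ``-``; a trailing ``*`` column is tolerated.
    """
    features: List[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score", "There were no")):
                continue
            fields = stripped.split()
            if len(fields) < 14:
                raise ValueError(f"{path}:{lineno}: unparseable row ({len(fields)} fields)")
            try:
                divergence = float(fields[1])
                seq_id = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                strand = fields[8]
                name = fields[9]
                class_family = fields[10]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row: {exc}") from None
            if begin < 1 or end < 1:
                raise ValueError(f"{path}:{lineno}: non-positive coordinate")
            if strand == "C":
                strand = "-"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            interval = GenomicInterval(
                seq_id,
                convert_coordinates(begin, "one_based_inclusive", "start"),
                convert_coordinates(end, "one_based_inclusive", "end"),
                strand,
            )
            features.append(RepeatFeature(interval, name, class_family, divergence))
    logger.info("read %d repeat features from %s", len(features), path)
    return features


def write_repeatmasker_out(features: Sequence[RepeatFeature], path: PathLike) -> None:
    """Write features in the standard ``.out`` layout (synthetic scores)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, feat in enumerate(features, start=1):
            iv = feat.interval
            begin = convert_coordinates(iv.start, "zero_based_half_open", "start")
            end = convert_coordinates(iv.end, "zero_based_half_open", "end")
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"{1000:>5} {feat.divergence_pct:>6.1f}  0.0  0.0  {iv.seq_id:<10}"
                f"{begin:>7} {end:>10} {'(0)':>9}   {strand} {feat.repeat_name:<16}"
                f"{feat.repeat_class_family:<18}{1:>6} {iv.length():>6} {'(0)':>7} {i:>4}\n"
            )


# ---------------------------------------------------------------------------
# BED / GFF3 gene models

@dataclass(frozen=True)
class GeneModel:
    """A transcription unit plus its exon intervals (may be empty for BED)."""

    name: str
    interval: GenomicInterval
    exons: Tuple[GenomicInterval, ...] = ()


def read_bed6(path: PathLike) -> List[GenomicInterval]:
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED row with <3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return intervals


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """Load gene models from BED6 (genes only) or GFF3 (gene + exon rows)."""
    path = Path(path)
    if path.suffix.lower() in (".bed",):
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED gene row needs >=4 columns")
                strand = fields[5] if len(fields) >= 6 else "."
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                genes.append(GeneModel(fields[3], iv))
        return genes
    return _read_gff3_genes(path)


_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _read_gff3_genes(path: PathLike) -> List[GeneModel]:
    genes: Dict[str, dict] = {}
    exons: List[Tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 row with {len(fields)} columns")
            seq_id, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "exon", "mRNA", "transcript"):
                continue
            attr = dict(_GFF_ATTR_RE.findall(attrs))
            iv = GenomicInterval(
                seq_id,
                convert_coordinates(int(start), "one_based_inclusive", "start"),
                convert_coordinates(int(end), "one_based_inclusive", "end"),
                strand if strand in ("+", "-") else ".",
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID attribute")
                genes[gid] = {"name": attr.get("Name", gid), "interval": iv, "exons": []}
            elif ftype in ("mRNA", "transcript"):
                # map transcript id onto its parent gene for exon grouping
                gid = attr.get("Parent")
                tid = attr.get("ID")
                if gid in genes and tid:
                    genes[tid] = genes[gid]
            else:  # exon
                parent = attr.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: exon without Parent attribute")
                exons.append((parent, iv))
    for parent, iv in exons:
        if parent in genes:
            genes[parent]["exons"].append(iv)
    out: List[GeneModel] = []
    seen = set()
    for rec in genes.values():
        key = id(rec)
        if key in seen:
            continue
        seen.add(key)
        out.append(GeneModel(rec["name"], rec["interval"],
                             tuple(sorted(rec["exons"], key=lambda e: e.start))))
    return out


# ---------------------------------------------------------------------------
# SVA substructure track

def write_sva_track(elements: Sequence[SVAElement], path: PathLike) -> None:
    """Write SVA elements with substructure as a BED-like track.

    One row per segment; column 4 is ``element_index:subfamily:segment_code``
    so elements can be reassembled on read.
    """
    with open(path, "w") as fh:
        for idx, el in enumerate(elements):
            for code, iv in el.segments:
                name = f"{idx}:{el.subfamily}:{int(code)}"
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{el.interval.strand}\n")


def read_sva_track(path: PathLike) -> List[SVAElement]:
    groups: Dict[Tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: SVA track row needs 6 columns")
            seq_id, start, end, name, _score, strand = fields[:6]
            try:
                idx, subfamily, code = name.split(":")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad segment name {name!r}") from None
            key = (seq_id, idx)
            rec = groups.setdefault(key, {"subfamily": subfamily, "strand": strand, "segs": []})
            rec["segs"].append((SvaSegment(int(code)),
                                GenomicInterval(seq_id, int(start), int(end), strand)))
    elements = []
    for (seq_id, _idx), rec in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[1]["segs"][0][1].start)):
        segs = sorted(rec["segs"], key=lambda s: s[1].start)
        iv = GenomicInterval(seq_id, segs[0][1].start, segs[-1][1].end, rec["strand"])
        elements.append(SVAElement(iv, rec["subfamily"], tuple(segs)))
    return elements


# ---------------------------------------------------------------------------
# calls TSV

_CALL_COLUMNS = [
    "locus_id", "event_type",
    "derived_seq", "derived_start_1", "derived_end_1",
    "ancestral_seq", "ancestral_start_1", "ancestral_end_1",
    "deletion_size", "mechanism", "microhomology_bp",
    "left_breakpoint", "right_breakpoint", "flags",
]


def _format_breakpoint(ann: Optional[BreakpointAnnotation]) -> str:
    if ann is None:
        return ""
    if ann.kind == BreakpointKind.UNIQUE:
        return "Unique"
    if ann.kind == BreakpointKind.SVA_SEGMENT:
        return f"SVA({int(ann.sva_segment_code)})"
    return ann.repeat_name or ""


def _parse_breakpoint(label: str) -> Optional[BreakpointAnnotation]:
    if not label:
        return None
    if label == "Unique":
        return BreakpointAnnotation(BreakpointKind.UNIQUE)
    m = re.fullmatch(r"SVA\((\d)\)", label)
    if m:
        return BreakpointAnnotation(BreakpointKind.SVA_SEGMENT,
                                    sva_segment_code=SvaSegment(int(m.group(1))))
    return BreakpointAnnotation(BreakpointKind.REPEAT, repeat_name=label)


def write_calls_tsv(calls: Sequence[DeletionCall], path: PathLike) -> None:
    """Write calls as a TSV with 1-based inclusive positions, sorted by position.

    A zero-length junction prints as ``(start_1, start_1 - 1)`` so that
    1-based inclusive lengths stay consistent.  SIMD rows leave the mechanism
    and microhomology cells empty.
    """
    rows = []
    for call in sorted(calls, key=lambda c: (c.derived_junction.seq_id,
                                             c.derived_junction.start,
                                             c.locus_id)):
        dj, ad = call.derived_junction, call.ancestral_deleted
        is_simd = call.event_type == EventType.SIMD
        rows.append({
            "locus_id": call.locus_id,
            "event_type": call.event_type.value,
            "derived_seq": dj.seq_id,
            "derived_start_1": dj.start + 1,
            "derived_end_1": dj.end,
            "ancestral_seq": ad.seq_id,
            "ancestral_start_1": ad.start + 1,
            "ancestral_end_1": ad.end,
            "deletion_size": call.deletion_size,
            "mechanism": "" if is_simd else call.mechanism.value,
            "microhomology_bp": "" if call.microhomology_bp is None else call.microhomology_bp,
            "left_breakpoint": _format_breakpoint(call.left_breakpoint_annotation),
            "right_breakpoint": _format_breakpoint(call.right_breakpoint_annotation),
            "flags": ";".join(call.flags),
        })
    df = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d calls to %s", len(rows), path)


def read_calls_tsv(path: PathLike) -> List[DeletionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    calls = []
    for _, row in df.iterrows():
        event = EventType(row["event_type"])
        mech = Mechanism(row["mechanism"]) if row["mechanism"] else Mechanism.NA
        mh = int(row["microhomology_bp"]) if row["microhomology_bp"] != "" else None
        calls.append(DeletionCall(
            event_type=event,
            locus_id=row["locus_id"],
            derived_junction=GenomicInterval(
                row["derived_seq"], int(row["derived_start_1"]) - 1, int(row["derived_end_1"])),
            ancestral_deleted=GenomicInterval(
                row["ancestral_seq"], int(row["ancestral_start_1"]) - 1, int(row["ancestral_end_1"])),
            deletion_size=int(row["deletion_size"]),
            microhomology_bp=mh,
            mechanism=mech,
            left_breakpoint_annotation=_parse_breakpoint(row["left_breakpoint"]),
            right_breakpoint_annotation=_parse_breakpoint(row["right_breakpoint"]),
            flags=tuple(f for f in row["flags"].split(";") if f),
        ))
    return calls


# ---------------------------------------------------------------------------
# packaged result-table fixtures

@dataclass(frozen=True)
class SradRow:
    locus_id: str
    printed_position: str
    deletion_size: int
    mechanism_label: str
    microhomology_bp: int


@dataclass(frozen=True)
class SimdRow:
    locus_id: str
    printed_position: str
    deletion_size: int


@dataclass(frozen=True)
class BreakpointRow:
    locus_id: str
    left_label: str
    right_label: str
    left_code: Optional[SvaSegment]
    right_code: Optional[SvaSegment]


@dataclass(frozen=True)
class PaperFixture:
    """The published per-locus tables, stored verbatim as packaged TSVs."""

    srad_rows: Tuple[SradRow, ...]
    simd_rows: Tuple[SimdRow, ...]
    breakpoint_rows: Tuple[BreakpointRow, ...]
    notes: Tuple[str, ...] = ()

    def srad(self, locus_id: str) -> SradRow:
        return next(r for r in self.srad_rows if r.locus_id == locus_id)

    def simd(self, locus_id: str) -> SimdRow:
        return next(r for r in self.simd_rows if r.locus_id == locus_id)

    def breakpoints(self, locus_id: str) -> BreakpointRow:
        return next(r for r in self.breakpoint_rows if r.locus_id == locus_id)


_FIXTURE_SHA256 = {
    "srad_loci.tsv": "2bcdeaf1c66ca866b3d20d6a909df2700fc69d39be4a398f8424bac53b768198",
    "simd_loci.tsv": "d1c7e3f902d51022968cebe06932a25724732a9bcc4e988c36f4e005c667989c",
    "srad_breakpoints.tsv": "2fb8c2b4c4f2830a6f51c4c8fe4424eb0987dd9d834413e7fd10039d5e9c07ee",
}

_FIXTURE_NOTES = (
    "SIMD locus 242: printed end coordinate 149099196 is inconsistent with its "
    "start (apparent typo in the source table); stored verbatim.",
    "SRAD locus 2493: the printed position span (95 bp) marks the chimeric "
    "element, not the 589 bp deletion; both stored as printed.",
)

_SEG_LABEL_RE = re.compile(r"\((\d)\)$")


def _fixture_text(name: str) -> str:
    data = resources.files("svadel").joinpath("data", name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} is corrupted (checksum mismatch)")
    return data.decode()


def _fixture_df(name: str) -> pd.DataFrame:
    from io import StringIO

    return pd.read_csv(StringIO(_fixture_text(name)), sep="\t", dtype=str)


def load_paper_fixture() -> PaperFixture:
    """Load the packaged per-locus result tables, verifying their checksums."""
    srad_df = _fixture_df("srad_loci.tsv")
    simd_df = _fixture_df("simd_loci.tsv")
    bp_df = _fixture_df("srad_breakpoints.tsv")

    srad_rows = tuple(
        SradRow(
            locus_id=r.locus,
            printed_position=f"{r.chrom}: {r.start_1based}-{r.end_1based}",
            deletion_size=int(r.deletion_size),
            mechanism_label=r.mechanism,
            microhomology_bp=int(r.microhomology_bp),
        )
        for r in srad_df.itertuples()
    )
    simd_rows = tuple(
        SimdRow(
            locus_id=r.locus,
            printed_position=f"{r.chrom}: {r.start_1based}-{r.end_1based}",
            deletion_size=int(r.deletion_size),
        )
        for r in simd_df.itertuples()
    )

    def code_of(label: str) -> Optional[SvaSegment]:
        m = _SEG_LABEL_RE.search(label)
        return SvaSegment(int(m.group(1))) if m else None

    bp_rows = tuple(
        BreakpointRow(r.locus, r.left_label, r.right_label,
                      code_of(r.left_label), code_of(r.right_label))
        for r in bp_df.itertuples()
    )

    fixture = PaperFixture(srad_rows, simd_rows, bp_rows, _FIXTURE_NOTES)
    if len(fixture.srad_rows) != 13 or len(fixture.simd_rows) != 13 \
            or len(fixture.breakpoint_rows) != 13:
        raise RuntimeError("fixture row counts differ from the published tables")
    srad_ids = {r.locus_id for r in fixture.srad_rows}
    if any(r.locus_id not in srad_ids for r in fixture.breakpoint_rows):
        raise RuntimeError("breakpoint fixture names a locus absent from the SRAD table")
    return fixture
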