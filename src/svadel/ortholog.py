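"""Locate and align the orthologous locus of an annotated SVA across genomes.

This is the pipeline's stand-in for a BLAT search: extract the element plus
flanking sequence from one genome, find the best-matching region of the
other genome by unique k-mer seeding and collinear chaining, then compute a
global affine-gap alignment of the locus pair.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None

from .align import AlignParams, Ops, align_ops
from .core import GenomicInterval, SVAElement

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR_K = 14
DEFAULT_MIN_ANCHOR_IDENTITY = 0.90
FLANK_BP_SRAD = 1000
FLANK_BP_SIMD = 2000


# ---------------------------------------------------------------------------
# locus extraction

@dataclass(frozen=True)
class ExtractedLocus:
    sequence: str
    interval: GenomicInterval
    clipped_left: bool = False
    clipped_right: bool = False


def extract_locus(sva: SVAElement, genome: Dict[str, str], flank_bp: int) -> ExtractedLocus:
    """Extract the SVA element plus ``flank_bp`` on each side, clipping at contig ends."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    iv = sva.interval
    if iv.seq_id not in genome:
        raise KeyError(f"contig {iv.seq_id!r} not in genome")
    contig = genome[iv.seq_id]
    if iv.end > len(contig):
        raise ValueError(f"SVA interval {iv} outside contig of length {len(contig)}")
    start = iv.start - flank_bp
    end = iv.end + flank_bp
    clipped_left = start < 0
    clipped_right = end > len(contig)
    start = max(start, 0)
    end = min(end, len(contig))
    out_iv = GenomicInterval(iv.seq_id, start, end, iv.strand)
    return ExtractedLocus(contig[start:end], out_iv, clipped_left, clipped_right)


# ---------------------------------------------------------------------------
# anchoring

class GenomeKmerIndex:
    """Exact k-mer position index over a genome, reusable across queries.

    k-mers occurring more than ``max_hits`` times (e.g. poly-A runs) are
    dropped from the index.
    """

    def __init__(self, genome: Dict[str, str], k: int, max_hits: int = 20):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.genome = genome
        index: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        overflow = set()
        for contig, seq in genome.items():
            s = seq.upper()
            for i in range(0, len(s) - k + 1):
                kmer = s[i:i + k]
                if kmer in overflow or "N" in kmer:
                    continue
                hits = index[kmer]
                hits.append((contig, i))
                if len(hits) > max_hits:
                    overflow.add(kmer)
                    del index[kmer]
        self.index = dict(index)

    def hits(self, kmer: str) -> List[Tuple[str, int]]:
        return self.index.get(kmer.upper(), [])


def _infix_identity(piece: str, region: str) -> float:
    """Identity of the best alignment of ``piece`` anywhere within ``region``."""
    if not piece:
        return 0.0
    if edlib is not None:
        res = edlib.align(piece.upper(), region.upper(), mode="HW", task="distance")
        return max(0.0, 1.0 - res["editDistance"] / len(piece))
    score, _ = align_ops(piece, region)  # pragma: no cover - edlib present in practice
    return max(0.0, score / len(piece))


def anchor_ortholog(
    query_seq: str,
    target_genome: Dict[str, str],
    k: int = DEFAULT_ANCHOR_K,
    min_anchor_identity: float = DEFAULT_MIN_ANCHOR_IDENTITY,
    flank_bp: Optional[int] = None,
    index: Optional[GenomeKmerIndex] = None,
    pad_bp: int = 200,
) -> Optional[GenomicInterval]:
    """Find the target-genome interval orthologous to ``query_seq``.

    Unique query k-mers are looked up in the target, hits are chained per
    contig (collinear, increasing), and the winning chain is extended to the
    full query projection plus ``pad_bp``.  The candidate is accepted only if
    both query flanks (the outer ``flank_bp`` bases; the whole query when
    None) align within the candidate at identity >= ``min_anchor_identity``.
    Returns None when no chain passes.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if len(query_seq) < 2 * k:
        raise ValueError("query shorter than 2k")
    if not target_genome or all(len(s) == 0 for s in target_genome.values()):
        raise ValueError("target genome is empty")
    if index is None:
        index = GenomeKmerIndex(target_genome, k)
    elif index.k != k:
        raise ValueError("prebuilt index k does not match")

    q = query_seq.upper()
    per_contig: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for i in range(0, len(q) - k + 1, max(1, k // 2)):
        kmer = q[i:i + k]
        if "N" in kmer:
            continue
        for contig, pos in index.hits(kmer):
            per_contig[contig].append((i, pos))
    if not per_contig:
        return None

    best: Optional[Tuple[int, str, List[Tuple[int, int]]]] = None
    for contig, pairs in per_contig.items():
        chain = _collinear_chain(sorted(pairs))
        if best is None or len(chain) > best[0]:
            best = (len(chain), contig, chain)
    if best is None or best[0] == 0:
        return None
    _, contig, chain = best
    contig_len = len(target_genome[contig])
    q0, t0 = chain[0]
    q1, t1 = chain[-1]
    start = max(0, t0 - q0 - pad_bp)
    end = min(contig_len, t1 + k + (len(q) - q1 - k) + pad_bp)
    if end <= start:
        return None

    region = target_genome[contig][start:end]
    fb = flank_bp if flank_bp is not None else len(query_seq)
    fb = min(fb, len(query_seq))
    left_id = _infix_identity(query_seq[:fb], region)
    right_id = _infix_identity(query_seq[-fb:], region)
    if left_id < min_anchor_identity or right_id < min_anchor_identity:
        logger.info("candidate at %s:%d-%d rejected (flank identity %.3f/%.3f)",
                    contig, start, end, left_id, right_id)
        return None
    return GenomicInterval(contig, start, end, "+")


def _collinear_chain(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Longest chain with strictly increasing query and target positions."""
    import bisect

    tails: List[int] = []
    tails_idx: List[int] = []
    parent = [-1] * len(pairs)
    for idx, (_q, t) in enumerate(pairs):
        pos = bisect.bisect_left(tails, t)
        if pos == len(tails):
            tails.append(t)
            tails_idx.append(idx)
        else:
            tails[pos] = t
            tails_idx[pos] = idx
        parent[idx] = tails_idx[pos - 1] if pos > 0 else -1
    if not tails_idx:
        return []
    chain = []
    cur = tails_idx[-1]
    while cur != -1:
        chain.append(pairs[cur])
        cur = parent[cur]
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# locus pairs

@dataclass(frozen=True)
class Block:
    """A gap-free aligned segment (local coordinates within the pair)."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.t_end - self.t_start:
            raise ValueError("block sides differ in length")


@dataclass(frozen=True)
class Gap:
    """An unaligned run between blocks.

    ``side`` names the sequence that is missing bases; the interval
    ``[start, end)`` spans the extra residues of the *other* sequence (local
    coordinates).  ``q_pos``/``t_pos`` locate the gap on both sequences.
    """

    side: str  # "query" or "target"
    q_start: int
    q_end: int
    t_start: int
    t_end: int

    @property
    def length(self) -> int:
        return (self.t_end - self.t_start) if self.side == "query" else (self.q_end - self.q_start)


@dataclass(frozen=True)
class LocusPair:
    """An orthologous locus pair with its pairwise alignment."""

    query_interval: GenomicInterval
    target_interval: GenomicInterval
    blocks: Tuple[Block, ...]
    gaps: Tuple[Gap, ...]
    score: int
    locus_id: str = ""


def align_pair(query_seq: str, target_seq: str,
               params: Optional[AlignParams] = None,
               max_len: int = 50_000) -> Tuple[int, Tuple[Block, ...], Tuple[Gap, ...]]:
    """Globally align a locus pair and decompose it into blocks and gaps.

    Raises for sequences above ``max_len`` (raise the cap explicitly for
    unusually long loci).
    """
    if not query_seq or not target_seq:
        raise ValueError("both sequences must be non-empty")
    if len(query_seq) > max_len or len(target_seq) > max_len:
        raise ValueError(
            f"sequence exceeds {max_len} bp cap; pass max_len explicitly to override")
    params = params or AlignParams()
    score, ops = align_ops(query_seq, target_seq, params)
    blocks, gaps = ops_to_blocks(query_seq, target_seq, ops)
    return score, blocks, gaps


def ops_to_blocks(query_seq: str, target_seq: str, ops: Ops
                  ) -> Tuple[Tuple[Block, ...], Tuple[Gap, ...]]:
    blocks: List[Block] = []
    gaps: List[Gap] = []
    qpos = tpos = 0
    for op, length in ops:
        if op == "M":
            matches = sum(
                1 for i in range(length)
                if query_seq[qpos + i].upper() == target_seq[tpos + i].upper()
                and query_seq[qpos + i].upper() != "N")
            blocks.append(Block(qpos, qpos + length, tpos, tpos + length,
                                matches, length - matches))
            qpos += length
            tpos += length
        elif op == "D":  # target-only bases -> gap on the query side
            gaps.append(Gap("query", qpos, qpos, tpos, tpos + length))
            tpos += length
        else:  # I: query-only bases -> gap on the target side
            gaps.append(Gap("target", qpos, qpos + length, tpos, tpos))
            qpos += length
    return tuple(blocks), tuple(gaps)


def build_locus_pair(query_interval: GenomicInterval, target_interval: GenomicInterval,
                     query_seq: str, target_seq: str,
                     params: Optional[AlignParams] = None,
                     locus_id: str = "") -> LocusPair:
    score, blocks, gaps = align_pair(query_seq, target_seq, params)
    return LocusPair(query_interval, target_interval, blocks, gaps, score, locus_id)
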