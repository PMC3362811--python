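# Methods

## Problem and model

Two genomes that diverged recently (the package's defaults target the ~1%
substitution regime of human vs chimpanzee) are compared around annotated SVA
retrotransposons.  Two deletion classes are called:

* **SRAD** — the SVA is present in both genomes, but the derived genome lacks
  a block of sequence whose ancestral footprint covers part of the element
  *and* adjacent non-element sequence (or parts of two elements).  The class
  splits mechanistically into NHEJ (short junction microhomology) and NAHR
  (recombination between the poly-A tails of two same-family elements,
  yielding one chimeric element).
* **SIMD** — the SVA is specific to the derived genome and the orthologous
  ancestral locus contains extra sequence at the insertion point: the
  insertion replaced target DNA.  A target-site duplication (>= 5 bp exact
  direct repeat flanking the element) instead marks a clean TPRT insertion
  and vetoes the call.

All internal coordinates are 0-based half-open; 1-based inclusive coordinates
exist only in the I/O layer (RepeatMasker `.out`, result tables).

## Pipeline stages

1. **Locus extraction.** Each derived-genome SVA annotation is extended by a
   flank (1,000 bp for the SRAD screen, 2,000 bp for the SIMD screen — the
   shared/derived-specific routing decides which applies); flanks are clipped
   at contig ends and the clipping recorded.
2. **Ortholog anchoring.** Unique k-mers (k = 14) of the query are looked up
   in a reusable index of the other genome (k-mers with > 20 hits, e.g.
   poly-A words, are dropped), hits are chained by longest collinear
   subsequence, and the winning chain is extended to the full query
   projection plus 200 bp of padding.  The candidate is accepted when both
   query flanks align within it at identity >= 0.90 (edit-distance identity
   via edlib in infix mode).  The identity window is clamped to the flank
   sequence actually remaining when a deletion has eaten into a flank.  Loci
   that fail anchoring are reported as *unmappable*, never silently dropped.
   The thresholds are this package's choice; the original screen's BLAT
   acceptance rules were not published numerically.
3. **Pairwise alignment.** Global affine-gap alignment (match +1, mismatch
   -2, gap open -5, gap extend -1; a length-g gap costs open + g·extend).
   Pairs whose DP table fits in 8M cells are solved exactly with a
   numpy-vectorized Gotoh DP; larger pairs are split on unique 32-mer anchor
   chains and the inter-anchor segments solved exactly (the oracle tests
   verify score-optimality on the exact path, and anchored-vs-exact agreement
   on planted cases).  Gaps are then shifted to their leftmost equivalent
   placement so breakpoint coordinates are deterministic; the microhomology
   stage reports the full shiftable range.
4. **Calling.** Derived-side gaps separated by matched islands <= 50 bp are
   merged: a deletion ending inside a tandem tract (the SVA VNTR has a 40 bp
   unit) legitimately fragments into gap pieces separated by islands of up to
   one repeat unit once substitutions make shifted placements locally
   optimal.  The deletion size is the *net* ancestral excess of the merged
   window, (t_span − q_span), which is exact under fragmentation; fragmented
   calls are flagged (`merged_k_gaps`).  SRADs require >= 50 bp (below that,
   alignment jitter); SIMDs require >= 1 bp because bona fide 14 bp target
   deletions occur.  For the SIMD screen the inserted element is excised from
   the derived locus before alignment, so ancestral-only sequence at the
   insertion point appears as a clean gap; without masking, the optimal
   affine alignment would pair the unrelated inserted and deleted sequences
   rather than open two long gaps.  Candidate deletions overlapping N runs in
   the unsequenced ancestral assembly are flagged `indeterminate_size` rather
   than resolved.
5. **Mechanism.** Junction microhomology is the exact-match extension (no
   mismatches, N never matches, case-insensitive) on both sides of the
   breakpoints.  NAHR requires homology >= `nahr_min_homology` (default 20
   bp) *and* both breakpoints inside annotated elements of the same repeat
   family; everything else is NHEJ.  The 20 bp default sits between the <= 7
   bp microhomology observed at NHEJ junctions in this event class and the 36
   bp poly-A homology of the observed NAHR event; no published threshold
   exists, so the value is configurable.
6. **Breakpoint typing.** A breakpoint inside an SVA substructure segment
   gets that segment's code (1 Alu-like, 2 VNTR, 3 SINE-R, 4 poly-A, 5
   hexamer, 6 SVA2-specific); a boundary position belongs to the downstream
   segment (half-open convention).  Otherwise the smallest covering repeat
   feature's name is used, else "unique".  SVA2 elements are absent from
   stock RepeatMasker libraries, so substructure comes from a user-supplied
   auxiliary track; the simulator emits one.
7. **Context.** Flank GC is GC / non-N bases over 10 kb on each side
   combined, against a *supplied* genome-wide reference (0.41 for human) —
   deliberately a config value, not a recomputed genome property.  The
   one-sample t-test defaults to the one-sided "greater" alternative (the
   question asked is whether SVA neighbourhoods are GC-richer); two-sided is
   available.  A zero-variance sample is reported as degenerate with the
   exact decision.  Genic context is exonic (>= 1 exon overlapped) >
   intragenic (inside any transcription unit) > intergenic.
8. **Summary.** Per event type: count, total bp, min/max/mean (mean displayed
   half-up to integer bp, e.g. 15752/13 → 1212; exact value retained),
   mechanism and segment-code tallies; combined total printed in kb at one
   decimal, half-up (46537 bp → 46.5).

## Synthetic-data generator

Each locus is an independent contig: 2,000 bp unique flanks (GC fraction
0.425, matching the flank GC observed around such loci) around a composite
SVA built from fixed per-subfamily template blocks — hexamer (CCCTCT)×3–8,
330 bp Alu-like body (an SVA2-specific body for SVA2), 40 bp VNTR unit ×
copies, 490 bp SINE-R, 16–40 bp poly-A.  The templates are synthetic
stand-ins generated from an internal fixed seed, not real repeat consensi;
downstream logic depends only on the block architecture, not on the letters.

Scenarios (default mix 23% NHEJ-SRAD, 2% NAHR-SRAD, 25% SIMD, 50% neutral;
drawn multinomially, so a 200-locus batch typically carries a small handful
of NAHR events, mirroring their observed rarity):

* **NHEJ-SRAD**: deletion sizes uniform in the observed 113–4,980 bp range
  (clipped to what a locus can host), spanning exactly one element boundary
  with >= 20 bp taken from each side; junction microhomology 0–7 bp is
  *engineered* — the m-word is copied to both breakpoints and the boundary
  bases rejection-fixed to mismatch — so the planted value is the unique
  maximal junction homology and recovery is well-posed.
* **NAHR-SRAD**: two same-subfamily elements with poly-A tails of exactly the
  configured homology length (36 bp, as observed) separated by 50–800 bp;
  the derived locus joins the 5' element through the shared poly-A to the
  second element's tail, and boundary bases are fixed so the measured
  homology equals the planted length exactly.
* **SIMD**: target deletions uniform in the observed 14–8,741 bp range,
  replaced by an element with no TSD (junction bases rejection-fixed until
  the TSD detector reports 0).
* **NEUTRAL**: shared element, no event.

Divergence is modelled as substitutions only (default 1.2%), applied to the
derived sequence outside a +/- 20 bp protected window around each planted
junction; event footprints stay >= 200 bp from contig ends so flank anchors
are always clean.  Per-locus RNG substreams are derived from (seed, locus
index), making batches byte-identical under a fixed seed and independent of
processing order.

**What passing recovery tests do and do not show.**  The generator reproduces
the coordinate arithmetic, junction structure and annotation geometry of real
events, but not indels in neutral sequence, VNTR length polymorphism between
genomes outside events, segmental duplication, assembly gaps (beyond explicit
N-run tests) or realistic primate mutation spectra.  Perfect recovery on
clean batches validates the pipeline's logic, not its performance on real
assemblies, where anchoring failures and repeat-density effects dominate
(the original screen resolved such loci by manual inspection and PCR).

## Packaged fixtures

The 13-locus SRAD table (positions, sizes, mechanisms, microhomology), the
13-locus SIMD table and the 13-locus breakpoint-type table are shipped as
TSVs with recorded SHA-256 checksums and loaded through
`svadel.load_paper_fixture()`.  Two source-table oddities are stored verbatim
and surfaced in the fixture notes rather than reconciled: SIMD locus 242's
printed end coordinate is inconsistent with its start (an apparent typo), and
SRAD locus 2493's printed 95 bp position span marks the chimeric element, not
its 589 bp deletion.  The printed subfamily tally table is internally
inconsistent (its SIMD column sums to 15 and its SRAD column to 12, against
13 loci each) and is therefore not used as a check; likewise the breakpoint
table shows one SINE-R breakpoint while the running text reports four SRADs
with SINE-R breakpoints — the fixture keeps the table as printed.

## Numerical and design choices

* Gap cost convention: open + g·extend (a 1 bp gap costs -6 under defaults).
* DP tie-breaks prefer the diagonal during traceback; canonical gap placement
  comes from the explicit left-shift pass, not from tie-break order.
* The merge width for split gaps defaults to 50 bp (one VNTR unit plus
  margin); at 10 bp, fragmented VNTR-tract deletions under 1% divergence are
  under-merged and their sizes misreported, which the recovery tests exposed.
* Problem sizes used by the test suite — 200-locus batches at substitution
  rates 0 and 0.01, loci of roughly 5–14 kb — keep the full recovery suite
  around half a minute while exercising every scenario including size
  extremes (14 bp and 8,741 bp SIMDs).
* `detect_tsd` reports the longest exact flanking repeat in 5–20 bp by
  default (cap 50); 5 bp is the shortest repeat distinguishable from chance
  at these flank lengths.
* Breakpoints are reported left-normalized; the shift range (length equal to
  the microhomology) is retained in the junction report.

## Limitations

Single-event-per-locus assumption in the caller (largest qualifying gap wins,
extras flagged `multiple_gaps`); no inversion/translocation handling; no
polymorphism within species; subfamily identity is taken from the annotation
input, not re-derived from sequence.  The genome-scale census numbers
(element counts per genome, per-chromosome distributions, real flank GC
percentages) require the real assemblies and are out of scope for the
desk-scale tests.
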