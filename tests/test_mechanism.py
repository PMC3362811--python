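"""Microhomology measurement and NHEJ/NAHR classification."""

import numpy as np
import pytest

from svadel.core import (
    DeletionCall,
    EventType,
    GenomicInterval,
    Mechanism,
    RepeatFeature,
)
from svadel.io import load_paper_fixture
from svadel.mechanism import (
    classify_mechanism,
    classify_mechanism_from_labels,
    measure_microhomology,
    render_junction_alignment,
)


def brute_force_microhomology(seq, L, R):
    """Independent maximization over all (j, k) pairs."""
    best_k = 0
    for k in range(0, R - L + 1):
        if R + k > len(seq):
            break
        a, b = seq[L:L + k].upper(), seq[R:R + k].upper()
        if a == b and "N" not in a:
            best_k = k
    best_j = 0
    for j in range(0, L + 1):
        a, b = seq[L - j:L].upper(), seq[R - j:R].upper()
        if a == b and "N" not in a:
            best_j = j
    return best_j, best_k


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


class TestMeasureMicrohomology:
    def test_distinct_blocks_give_zero(self):
        rep = measure_microhomology("AAACCCGGGTTT", 3, 9)
        assert rep.microhomology_bp == 0
        assert rep.shift_range == (3, 3)

    def test_planted_four_bp_word(self):
        # TAGC at both sides of the junction: seq[2:6] == seq[11:15]
        seq = "GGTAGCCCCCCTAGCGG"
        rep = measure_microhomology(seq, 2, 11)
        assert rep.right_ext_bp == 4 and rep.left_ext_bp == 0
        assert rep.microhomology_bp == 4
        assert rep.shift_range == (2, 6)

    def test_n_never_matches(self):
        rep = measure_microhomology("AANTTAANTT", 2, 7)
        assert rep.right_ext_bp == 0  # N at L blocks extension

    def test_equals_bruteforce_on_random_triples(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 120))
            seq = random_dna(rng, n, "ACGTN" if rng.random() < 0.3 else "ACGT")
            L = int(rng.integers(0, n - 1))
            R = int(rng.integers(L + 1, n + 1))
            rep = measure_microhomology(seq, L, R)
            j, k = brute_force_microhomology(seq, L, R)
            assert (rep.left_ext_bp, rep.right_ext_bp) == (j, k), (seq, L, R)

    def test_shift_invariance(self, rng):
        """Every breakpoint placement in the shift range yields the same
        derived sequence and the same total microhomology."""
        for _ in range(50):
            seq = random_dna(rng, 80)
            L = int(rng.integers(10, 40))
            R = int(rng.integers(L + 5, 75))
            rep = measure_microhomology(seq, L, R)
            derived = seq[:L] + seq[R:]
            for shift in range(-rep.left_ext_bp, rep.right_ext_bp + 1):
                assert seq[:L + shift] + seq[R + shift:] == derived
                rep2 = measure_microhomology(seq, L + shift, R + shift)
                assert rep2.microhomology_bp == rep.microhomology_bp
                assert rep2.shift_range == rep.shift_range

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            measure_microhomology("ACGT", 3, 3)
        with pytest.raises(ValueError):
            measure_microhomology("ACGT", 1, 9)


class TestClassifyMechanism:
    def _srad(self, L, R):
        return DeletionCall(EventType.SRAD, "x", GenomicInterval("d", 0, 0),
                            GenomicInterval("a", L, R), R - L)

    def test_high_homology_same_family_is_nahr(self):
        svas = [RepeatFeature(GenomicInterval("a", 50, 150), "SVA_A", "Retroposon/SVA"),
                RepeatFeature(GenomicInterval("a", 500, 700), "SVA_A", "Retroposon/SVA")]
        from svadel.mechanism import JunctionReport

        rep = JunctionReport(0, 36, (100, 136))
        assert classify_mechanism(self._srad(100, 600), rep, svas) == Mechanism.NAHR

    def test_low_homology_is_nhej_even_in_same_family(self):
        svas = [RepeatFeature(GenomicInterval("a", 50, 700), "SVA_A", "Retroposon/SVA")]
        from svadel.mechanism import JunctionReport

        rep = JunctionReport(0, 7, (100, 107))
        assert classify_mechanism(self._srad(100, 600), rep, svas) == Mechanism.NHEJ

    def test_high_homology_unique_breakpoint_is_nhej(self):
        svas = [RepeatFeature(GenomicInterval("a", 50, 150), "SVA_A", "Retroposon/SVA")]
        from svadel.mechanism import JunctionReport

        rep = JunctionReport(0, 25, (100, 125))
        assert classify_mechanism(self._srad(100, 600), rep, svas) == Mechanism.NHEJ


class TestFixtureClassification:
    def test_twelve_nhej_one_nahr(self):
        fx = load_paper_fixture()
        results = {}
        for row in fx.srad_rows:
            bp = fx.breakpoints(row.locus_id)
            results[row.locus_id] = classify_mechanism_from_labels(
                row.microhomology_bp, bp.left_label, bp.right_label)
        assert sum(1 for m in results.values() if m == Mechanism.NHEJ) == 12
        assert sum(1 for m in results.values() if m == Mechanism.NAHR) == 1

    def test_nahr_locus_is_polya_polya_with_36bp(self):
        fx = load_paper_fixture()
        nahr = [r for r in fx.srad_rows
                if classify_mechanism_from_labels(
                    r.microhomology_bp,
                    fx.breakpoints(r.locus_id).left_label,
                    fx.breakpoints(r.locus_id).right_label) == Mechanism.NAHR]
        assert len(nahr) == 1
        row = nahr[0]
        assert row.microhomology_bp == 36
        bp = fx.breakpoints(row.locus_id)
        assert int(bp.left_code) == 4 and int(bp.right_code) == 4

    def test_agrees_with_printed_mechanism_column(self):
        fx = load_paper_fixture()
        for row in fx.srad_rows:
            bp = fx.breakpoints(row.locus_id)
            got = classify_mechanism_from_labels(row.microhomology_bp,
                                                 bp.left_label, bp.right_label)
            assert got.value == row.mechanism_label


class TestJunctionRendering:
    def test_zero_microhomology_has_no_bracket(self, rng):
        seq = random_dna(rng, 200)
        L, R = 80, 150
        from svadel.mechanism import measure_microhomology

        rep = measure_microhomology(seq, L, R)
        text = render_junction_alignment(seq, L, R, context_bp=30)
        if rep.microhomology_bp == 0:
            assert "^" not in text

    def test_identical_context_rows_render_dots(self):
        seq = "ACGTACGTAC" + "GGGGGGGGGG" + "ACGTACGTAC"
        text = render_junction_alignment(seq, 12, 18, context_bp=5)
        lines = text.splitlines()
        assert lines[0].startswith("derived")
        assert len(lines) >= 3

    def test_context_smaller_than_homology_rejected(self):
        seq = "G" + "TTTTTTTTTTTTTTTTTTTT" + "C" * 30
        with pytest.raises(ValueError):
            render_junction_alignment(seq, 5, 15, context_bp=2)
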