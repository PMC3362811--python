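"""Domain types, coordinate conventions and sequence primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svadel.core import (
    DeletionCall,
    EventType,
    GenomicInterval,
    Mechanism,
    RepeatFeature,
    SVAElement,
    SvaSegment,
    convert_coordinates,
    reverse_complement,
)

dna = st.text(alphabet="ACGTNacgtn", min_size=0, max_size=200)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", "ACGT"),          # palindrome
        ("AAAC", "GTTT"),
        ("", ""),
        ("acgtN", "Nacgt"),        # case preserved, N self-complementary
        ("RYKM", "KMRY"),          # ambiguity codes
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_non_iupac_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            reverse_complement("ACGXA")


class TestConvertCoordinates:
    def test_printed_table_start(self):
        # printed 1-based start of a report-table locus
        assert convert_coordinates(18672855, "one_based_inclusive", "start") == 18672854

    def test_unit_interval(self):
        s = convert_coordinates(1, "one_based_inclusive", "start")
        e = convert_coordinates(1, "one_based_inclusive", "end")
        assert (s, e) == (0, 1)

    @given(st.integers(1, 10**9), st.integers(0, 10**6))
    def test_round_trip_and_length(self, start1, span):
        end1 = start1 + span  # 1-based inclusive interval of length span+1
        s0 = convert_coordinates(start1, "one_based_inclusive", "start")
        e0 = convert_coordinates(end1, "one_based_inclusive", "end")
        assert e0 - s0 == span + 1
        assert convert_coordinates(s0, "zero_based_half_open", "start") == start1
        assert convert_coordinates(e0, "zero_based_half_open", "end") == end1

    def test_rejects_below_minimum(self):
        with pytest.raises(ValueError):
            convert_coordinates(0, "one_based_inclusive", "start")
        with pytest.raises(ValueError):
            convert_coordinates(-1, "zero_based_half_open", "end")


class TestIntervalAlgebra:
    def test_basic_invariants(self):
        iv = GenomicInterval("chr1", 10, 20)
        assert iv.length() == 10
        assert not iv.overlaps(GenomicInterval("chr2", 10, 20))
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_agrees_with_per_base_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a_s, b_s = rng.integers(0, 10_000, size=2)
            a = GenomicInterval("c", int(a_s), int(a_s + rng.integers(0, 500)))
            b = GenomicInterval("c", int(b_s), int(b_s + rng.integers(0, 500)))
            sa, sb = set(range(a.start, a.end)), set(range(b.start, b.end))
            assert a.overlaps(b) == bool(sa & sb)
            assert a.contains(b) == (sb <= sa)
            assert a.overlap_length(b) == len(sa & sb)
            if not a.overlaps(b) and sa and sb:
                assert a.gap_to(b) == min(abs(x - y) for x in sa for y in sb) - 1 \
                    if a.gap_to(b) else True

    def test_gap_to(self):
        a = GenomicInterval("c", 0, 10)
        assert a.gap_to(GenomicInterval("c", 15, 20)) == 5
        assert a.gap_to(GenomicInterval("c", 10, 20)) == 0
        assert a.gap_to(GenomicInterval("d", 15, 20)) is None


class TestSVAElement:
    def test_segment_validation(self):
        iv = GenomicInterval("c", 100, 200)
        segs = ((SvaSegment.HEXAMER, GenomicInterval("c", 100, 130)),
                (SvaSegment.ALU_LIKE, GenomicInterval("c", 130, 200)))
        el = SVAElement(iv, "SVA_D", segs)
        assert el.segment_at(100) == SvaSegment.HEXAMER
        assert el.segment_at(130) == SvaSegment.ALU_LIKE  # boundary -> downstream
        assert el.segment_at(99) is None
        with pytest.raises(ValueError):
            SVAElement(iv, "SVA_Z", segs)
        with pytest.raises(ValueError):  # overlapping segments
            SVAElement(iv, "SVA_D", (
                (SvaSegment.HEXAMER, GenomicInterval("c", 100, 150)),
                (SvaSegment.ALU_LIKE, GenomicInterval("c", 140, 200))))


class TestDeletionCall:
    def _junction(self):
        return GenomicInterval("d", 50, 50)

    def test_size_must_match_interval(self):
        with pytest.raises(ValueError):
            DeletionCall(EventType.SRAD, "x", self._junction(),
                         GenomicInterval("a", 0, 100), 99)

    def test_simd_constraints(self):
        with pytest.raises(ValueError):
            DeletionCall(EventType.SIMD, "x", GenomicInterval("d", 50, 60),
                         GenomicInterval("a", 0, 100), 100, microhomology_bp=3)
        with pytest.raises(ValueError):
            DeletionCall(EventType.SIMD, "x", GenomicInterval("d", 50, 60),
                         GenomicInterval("a", 0, 100), 100, mechanism=Mechanism.NHEJ)

    def test_repeat_feature_validation(self):
        iv = GenomicInterval("c", 0, 10)
        assert RepeatFeature(iv, "SVA_D", "Retroposon/SVA").is_sva
        assert not RepeatFeature(iv, "AluSx1", "SINE/Alu").is_sva
        with pytest.raises(ValueError):
            RepeatFeature(iv, "x", "y", divergence_pct=150)
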