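"""Deletion calling: SRAD/SIMD decision rules and TSD detection."""

import numpy as np
import pytest

from svadel.calling import call_simd, call_srad, detect_tsd, merge_query_gaps
from svadel.core import EventType, GenomicInterval, RepeatFeature, SVAElement, SvaSegment
from svadel.ortholog import Gap, build_locus_pair
from svadel.simulate import build_sva_sequence, plant_nhej_srad


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _shared_locus(rng, flank=2000):
    sva_seq, segs = build_sva_sequence("SVA_D", 8, rng)
    locus = random_dna(rng, flank) + sva_seq + random_dna(rng, flank)
    element = SVAElement(
        GenomicInterval("L", flank, flank + len(sva_seq), "+"), "SVA_D",
        tuple((c, GenomicInterval("L", flank + s, flank + e, "+")) for c, (s, e) in segs))
    feature = RepeatFeature(element.interval, "SVA_D", "Retroposon/SVA", 2.0)
    return locus, element, feature


def _pair(query, target, locus_id="L"):
    return build_locus_pair(GenomicInterval("L", 0, len(query)),
                            GenomicInterval("L", 0, len(target)),
                            query, target, locus_id=locus_id)


class TestCallSrad:
    def test_planted_deletion_called_exactly(self, rng):
        locus, sva, feat = _shared_locus(rng)
        anc, der, truth = plant_nhej_srad(locus, sva, 1017, 4, rng)
        pair = _pair(der, anc)
        call = call_srad(pair, [feat], [feat], ancestral_seq=anc)
        assert call is not None
        assert call.event_type == EventType.SRAD
        assert call.deletion_size == 1017
        assert call.ancestral_deleted == truth.ancestral_deleted

    def test_pure_vntr_contraction_is_not_an_srad(self, rng):
        locus, sva, feat = _shared_locus(rng)
        vntr = next(iv for c, iv in sva.segments if c == SvaSegment.VNTR)
        # remove 4 whole VNTR units: gap entirely inside the element
        der = locus[:vntr.start] + locus[vntr.start + 160:]
        call = call_srad(_pair(der, locus), [feat], [feat])
        assert call is None

    def test_neutral_locus_no_call(self, rng):
        locus, sva, feat = _shared_locus(rng)
        call = call_srad(_pair(locus, locus), [feat], [feat])
        assert call is None

    def test_deletion_below_threshold_ignored(self, rng):
        locus, sva, feat = _shared_locus(rng)
        anc, der, truth = plant_nhej_srad(locus, sva, 120, 0, rng)
        assert call_srad(_pair(der, anc), [feat], [feat], min_deletion_bp=500) is None

    def test_n_run_flags_indeterminate(self, rng):
        locus, sva, feat = _shared_locus(rng)
        anc, der, truth = plant_nhej_srad(locus, sva, 600, 0, rng)
        L = truth.ancestral_deleted.start
        anc_n = anc[:L + 50] + "N" * 30 + anc[L + 80:]
        pair = _pair(der, anc_n)
        call = call_srad(pair, [feat], [feat], ancestral_seq=anc_n)
        assert call is not None
        assert "indeterminate_size" in call.flags


class TestCallSimd:
    def _simd_setup(self, rng, d, flank=2000):
        sva_seq, _ = build_sva_sequence("SVA_D", 6, rng)
        anc = random_dna(rng, 2 * flank + d)
        der = anc[:flank] + sva_seq + anc[flank + d:]
        masked = der[:flank] + der[flank + len(sva_seq):]
        pair = _pair(masked, anc)
        return pair, GenomicInterval("L", flank, flank + len(sva_seq)), der, anc

    @pytest.mark.parametrize("d", [14, 8741])
    def test_planted_target_deletion_recovered(self, rng, d):
        pair, ins, der, anc = self._simd_setup(rng, d)
        call, tsd = call_simd(pair, ins, der, ancestral_seq=anc)
        assert call is not None
        assert call.event_type == EventType.SIMD
        assert call.deletion_size == d
        assert tsd == 0
        assert call.microhomology_bp is None

    def test_clean_tprt_insertion_with_tsd_is_not_a_simd(self, rng):
        sva_seq, _ = build_sva_sequence("SVA_D", 6, rng)
        flank = 2000
        anc = random_dna(rng, 2 * flank)
        tsd = anc[flank - 15:flank]
        # insertion duplicates the 15 bp target site, deletes nothing
        der = anc[:flank] + sva_seq + tsd + anc[flank:]
        ins = GenomicInterval("L", flank, flank + len(sva_seq) + 15)
        # alignment view: mask the inserted element plus its 3' TSD copy end
        masked = der[:flank] + der[flank + len(sva_seq):]
        pair = _pair(masked, anc)
        call, tsd_bp = call_simd(pair, GenomicInterval("L", flank, flank + len(sva_seq)),
                                 der, min_deletion_bp=1)
        assert call is None
        assert tsd_bp == 15


class TestDetectTsd:
    def test_constructed_example(self):
        seq = "GGGG" + "AGTCA" + "X" * 0 + "TTTTTTTT" + "AGTCA" + "GGGG"
        # insertion [9, 17) flanked by AGTCA on both sides
        assert detect_tsd(seq, GenomicInterval("", 9, 17), 20) == 5

    def test_no_duplication_returns_zero(self, rng):
        seq = random_dna(rng, 200)
        assert detect_tsd(seq, GenomicInterval("", 100, 150), 20) in range(0, 5)

    def test_equals_bruteforce_scan(self, rng):
        for _ in range(200):
            n = int(rng.integers(60, 160))
            seq = random_dna(rng, n)
            s = int(rng.integers(25, n - 25))
            e = int(rng.integers(s, n - 25))
            got = detect_tsd(seq, GenomicInterval("", s, e), 20)
            brute = 0
            for k in range(5, 21):
                if s - k >= 0 and e + k <= n and seq[s - k:s] == seq[e:e + k]:
                    brute = max(brute, k)
            assert got == brute

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            detect_tsd("ACGT", GenomicInterval("", 2, 10), 20)
        with pytest.raises(ValueError):
            detect_tsd("ACGT" * 100, GenomicInterval("", 10, 20), 60)


class TestGapMerging:
    def test_fragmented_gap_merges_with_net_size(self):
        gaps = (Gap("query", 100, 100, 100, 200),
                Gap("query", 110, 110, 210, 260),
                Gap("query", 300, 300, 450, 500))
        merged = merge_query_gaps(gaps, merge_bp=20)
        assert len(merged) == 2
        assert merged[0].net_bp == (260 - 100) - (110 - 100)
        assert merged[0].n_gaps == 2

    def test_target_side_gaps_ignored(self):
        gaps = (Gap("target", 100, 150, 100, 100),)
        assert merge_query_gaps(gaps) == []
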