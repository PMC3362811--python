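"""Synthetic-genome generator: element assembly, planting ops, batch determinism."""

import numpy as np
import pytest

from svadel.core import GenomicInterval, SVAElement, SvaSegment
from svadel.mechanism import measure_microhomology
from svadel.simulate import (
    SimulationConfig,
    build_sva_sequence,
    plant_nahr_srad,
    plant_nhej_srad,
    plant_simd,
    simulate_batch,
    write_batch,
)


class TestBuildSva:
    def test_vntr_arithmetic(self, rng):
        seq, segs = build_sva_sequence("SVA_D", vntr_copies=3, rng=rng)
        vntr = next(iv for code, iv in segs if code == SvaSegment.VNTR)
        assert vntr[1] - vntr[0] == 120  # 3 x 40 bp unit

    def test_segment_order_and_contiguity(self, rng):
        seq, segs = build_sva_sequence("SVA_B", 5, rng)
        codes = [int(c) for c, _ in segs]
        assert codes == [5, 1, 2, 3, 4]  # hexamer, Alu-like, VNTR, SINE-R, poly-A
        pos = 0
        for _, (s, e) in segs:
            assert s == pos
            pos = e
        assert pos == len(seq)

    def test_sva2_specific_block(self, rng):
        _, segs = build_sva_sequence("SVA2", 5, rng)
        assert [int(c) for c, _ in segs] == [5, 6, 2, 3, 4]

    def test_deterministic_under_seed(self):
        a = build_sva_sequence("SVA_C", 4, np.random.default_rng(5))
        b = build_sva_sequence("SVA_C", 4, np.random.default_rng(5))
        assert a == b

    def test_rejects_bad_vntr_copies(self, rng):
        with pytest.raises(ValueError):
            build_sva_sequence("SVA_D", 0, rng)


def _shared_locus(rng, flank=2000):
    sva_seq, segs = build_sva_sequence("SVA_D", 8, rng)
    left = "".join(np.array(list("ACGT"))[rng.integers(0, 4, flank)])
    right = "".join(np.array(list("ACGT"))[rng.integers(0, 4, flank)])
    locus = left + sva_seq + right
    element = SVAElement(
        GenomicInterval("L", flank, flank + len(sva_seq), "+"), "SVA_D",
        tuple((c, GenomicInterval("L", flank + s, flank + e, "+")) for c, (s, e) in segs))
    return locus, element


class TestPlantNhej:
    @pytest.mark.parametrize("m", [0, 2, 7])
    def test_planted_microhomology_is_measurable(self, rng, m):
        locus, sva = _shared_locus(rng)
        anc, der, truth = plant_nhej_srad(locus, sva, 600, m, rng)
        L, R = truth.ancestral_deleted.start, truth.ancestral_deleted.end
        assert measure_microhomology(anc, L, R).microhomology_bp == m
        assert truth.microhomology_bp == m

    def test_length_conservation(self, rng):
        for size in (150, 1017, 2500):
            locus, sva = _shared_locus(rng)
            anc, der, truth = plant_nhej_srad(locus, sva, size, 3, rng)
            assert len(der) == len(anc) - size
            assert der == anc[:truth.ancestral_deleted.start] + \
                anc[truth.ancestral_deleted.end:]

    def test_spans_element_boundary(self, rng):
        locus, sva = _shared_locus(rng)
        anc, der, truth = plant_nhej_srad(locus, sva, 500, 2, rng, boundary="right")
        d = truth.ancestral_deleted
        assert d.start < sva.interval.end <= d.end  # part element, part flank

    def test_microhomology_must_fit(self, rng):
        locus, sva = _shared_locus(rng)
        with pytest.raises(ValueError):
            plant_nhej_srad(locus, sva, 100, 100, rng)

    def test_oversized_deletion_rejected(self, rng):
        locus, sva = _shared_locus(rng, flank=500)
        with pytest.raises(ValueError):
            plant_nhej_srad(locus, sva, 20_000, 2, rng)


class TestPlantNahr:
    def test_poly_a_homology_recovered(self, rng):
        anc, der, truth, anc_els, der_els = plant_nahr_srad(
            "L", "SVA_A", 2000, 300, 36, 0.42, rng)
        L, R = truth.ancestral_deleted.start, truth.ancestral_deleted.end
        assert measure_microhomology(anc, L, R).microhomology_bp == 36
        assert truth.breakpoint_segment_codes == (SvaSegment.POLY_A, SvaSegment.POLY_A)

    def test_chimera_is_single_element(self, rng):
        anc, der, truth, anc_els, der_els = plant_nahr_srad(
            "L", "SVA_B", 2000, 200, 36, 0.42, rng)
        assert len(anc_els) == 2 and len(der_els) == 1
        # chimera = full-length element architecture
        assert [int(c) for c, _ in der_els[0].segments] == [5, 1, 2, 3, 4]

    def test_deletion_size_from_planted_coordinates(self, rng):
        anc, der, truth, anc_els, _ = plant_nahr_srad(
            "L", "SVA_C", 2000, 250, 36, 0.42, rng)
        sva1, sva2 = anc_els
        L = sva1.interval.end - 36
        R = sva2.interval.end - 36
        assert truth.ancestral_deleted == GenomicInterval("L", L, R)
        assert truth.deletion_size == R - L
        assert len(der) == len(anc) - truth.deletion_size

    def test_poly_a_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_nahr_srad("L", "SVA_A", 2000, 200, 3, 0.42, rng)


class TestPlantSimd:
    @pytest.mark.parametrize("d", [14, 8741])
    def test_observed_extremes(self, rng, d):
        sva_seq, _ = build_sva_sequence("SVA_D", 6, rng)
        locus = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000 + d)])
        anc, der, truth = plant_simd(locus, sva_seq, d, 2000, rng)
        assert truth.deletion_size == d
        assert len(der) == len(anc) - d + len(sva_seq)

    def test_no_target_site_duplication(self, rng):
        from svadel.calling import detect_tsd

        sva_seq, _ = build_sva_sequence("SVA_D", 6, rng)
        locus = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        anc, der, truth = plant_simd(locus, sva_seq, 500, 2000, rng)
        assert detect_tsd(der, GenomicInterval("", 2000, 2000 + len(sva_seq)), 20) == 0

    def test_bad_size_rejected(self, rng):
        sva_seq, _ = build_sva_sequence("SVA_D", 6, rng)
        with pytest.raises(ValueError):
            plant_simd("ACGT" * 2000, sva_seq, 0, 2000, rng)


class TestSimulateBatch:
    def test_byte_identical_outputs_under_seed(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_loci=8)
        p1 = write_batch(simulate_batch(cfg), tmp_path / "a")
        p2 = write_batch(simulate_batch(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_scenario_counts_bookkeeping(self):
        cfg = SimulationConfig(seed=5, n_loci=40)
        batch = simulate_batch(cfg)
        assert len(batch.truths) == 40
        assert {t.scenario for t in batch.truths} <= {
            "NHEJ_SRAD", "NAHR_SRAD", "SIMD", "NEUTRAL"}

    def test_all_srad_mix_gives_13_truth_rows(self):
        cfg = SimulationConfig(seed=1, n_loci=13,
                               scenario_mix={"NHEJ_SRAD": 1.0})
        batch = simulate_batch(cfg)
        assert len(batch.truths) == 13
        assert all(t.scenario == "NHEJ_SRAD" for t in batch.truths)

    def test_length_conservation_every_locus(self):
        cfg = SimulationConfig(seed=9, n_loci=20, substitution_rate=0.0)
        batch = simulate_batch(cfg)
        for loc in batch.loci:
            inserted = sum(el.interval.length() for el in loc.derived_elements) \
                if loc.truth.scenario == "SIMD" else 0
            if loc.truth.scenario == "SIMD":
                expect = len(loc.ancestral_seq) - loc.truth.deletion_size + inserted
            else:
                expect = len(loc.ancestral_seq) - loc.truth.deletion_size
            assert len(loc.derived_seq) == expect, loc.truth

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario_mix={"NHEJ_SRAD": 0.4})
        with pytest.raises(ValueError):
            SimulationConfig(scenario_mix={"BANANA": 1.0})
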