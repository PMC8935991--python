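import math

import numpy as np
import pytest

from bsascan.filters import FilterConfig, apply_filters
from bsascan.null_simulation import BulkDesign, segregation_probs
from bsascan.synthetic_data import (SyntheticScenario, default_scenario,
                                    expected_bulk_freq, generate_vcf,
                                    haldane_r, linked_genotype_probs,
                                    marker_distance_cm, write_scenario)
from bsascan.vcf_io import GenomeInfo, SampleRoles, read_variants


class TestHaldaneExpectation:
    def test_recombination_fraction_at_10_cm(self):
        # hand evaluation: r = 0.5*(1 - e^-0.2) = 0.090634623
        assert haldane_r(10.0) == pytest.approx(0.090635, abs=5e-7)

    def test_expected_freq_at_10_cm(self):
        sc = default_scenario()
        pos = sc.causal[1] + int(10 / sc.cm_per_mb * 1e6)  # 10 cM away
        (f,) = expected_bulk_freq("chr1", pos, sc)
        assert f == pytest.approx(0.909365, abs=5e-7)

    def test_marker_at_causal_position(self):
        sc1 = default_scenario("one-bulk")
        assert expected_bulk_freq("chr1", 5_000_000, sc1) == (1.0,)
        sc2 = default_scenario("two-bulk")
        f1, f2 = expected_bulk_freq("chr1", 5_000_000, sc2)
        assert f1 - f2 == pytest.approx(1.0)

    def test_unlinked_chromosome_is_half(self):
        sc = default_scenario("two-bulk")
        assert marker_distance_cm("chr2", 1, sc) == math.inf
        assert expected_bulk_freq("chr2", 1, sc) == (0.5, 0.5)


class TestLinkedGenotypeProbs:
    def test_f2_conditional_is_binomial_in_one_minus_r(self):
        r = 0.2
        probs = linked_genotype_probs(r, 2, causal_count=2)
        expected = [r**2, 2 * r * (1 - r), (1 - r) ** 2]
        assert probs == pytest.approx(expected)

    def test_unlinked_reduces_to_segregation_ratios(self):
        for k in (2, 6):
            probs = linked_genotype_probs(0.5, k, causal_count=2)
            assert probs == pytest.approx(segregation_probs(k).as_array())

    def test_f3_matches_explicit_gamete_simulation(self):
        """Independent oracle: simulate F1 -> F2 -> F3 selfing with explicit
        gamete draws and selection on the causal genotype."""
        r, reps = 0.2, 60_000
        rng = np.random.default_rng(99)

        def gamete(diplo):
            h1, h2 = diplo
            i = rng.integers(2)
            j = i if rng.random() < 1 - r else 1 - i
            pair = (h1, h2)
            return (pair[i][0], pair[j][1])

        counts = np.zeros(3)
        n_acc = 0
        while n_acc < reps:
            indiv = (((0, 0), (1, 1)))  # F1 coupling heterozygote
            for _ in range(2):  # two selfing generations: F3
                indiv = (gamete(indiv), gamete(indiv))
            if indiv[0][0] + indiv[1][0] == 2:  # selected hom non-parental
                counts[indiv[0][1] + indiv[1][1]] += 1
                n_acc += 1
        sim = counts / reps
        exact = linked_genotype_probs(r, 3, causal_count=2)
        assert sim == pytest.approx(exact, abs=0.01)


class TestGenerateVcf:
    def test_causal_marker_is_fully_non_parental_without_error(self):
        sc = default_scenario(seed=5)
        text, truth = generate_vcf(sc)
        line = next(l for l in text.splitlines()
                    if l.startswith("chr1\t5000000\t"))
        bulk = line.split("\t")[-1]
        assert bulk == "1/1:0,100"
        row = next(r for r in truth if r["CHROM"] == "chr1" and r["POS"] == 5_000_000)
        assert row["TRUE_FREQ_BULK1"] == 1.0 and row["DIST_CM"] == 0.0

    def test_fixed_depth_model_sums_to_depth(self, small_synth_vcf, one_bulk_roles):
        for v in read_variants(str(small_synth_vcf), one_bulk_roles):
            assert v.parent.depth == 100
            assert v.bulks[0].depth == 100

    def test_round_trip_through_vcf_io_keeps_every_record(self, tmp_path):
        sc = default_scenario(seed=1, n_variants=200)
        vcf, truth_p = tmp_path / "s.vcf", tmp_path / "t.tsv"
        write_scenario(sc, str(vcf), str(truth_p))
        variants = list(read_variants(str(vcf), SampleRoles("PARENT", "BULK1")))
        _, truth = generate_vcf(sc)
        assert len(variants) == len(truth)
        # no record is rejected for missing fields: parent always called at depth
        cfg = FilterConfig()
        assert all("MISSING_PARENT" not in apply_filters(v, cfg, "one-bulk").reasons
                   for v in variants)

    def test_high_depth_limit_tracks_finite_bulk_truth(self):
        sc = default_scenario(seed=3, n_variants=100, depth_mean=100_000)
        text, truth = generate_vcf(sc)
        rows = {(r["CHROM"], r["POS"]): r for r in truth}
        for line in text.splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            ref_d, alt_d = map(int, f[9 + 1].split(":")[1].split(","))
            observed = alt_d / (ref_d + alt_d)
            truth_f = rows[(f[0], int(f[1]))]["TRUE_FREQ_BULK1"]
            assert abs(observed - truth_f) < 0.01

    def test_two_bulk_delta_structure(self):
        sc = default_scenario("two-bulk", seed=8, n_variants=600)
        _, truth = generate_vcf(sc)
        causal = next(r for r in truth if r["POS"] == 5_000_000 and r["CHROM"] == "chr1")
        assert causal["TRUE_FREQ_BULK1"] - causal["TRUE_FREQ_BULK2"] == pytest.approx(1.0)
        unlinked = [r["TRUE_FREQ_BULK1"] - r["TRUE_FREQ_BULK2"]
                    for r in truth if r["CHROM"] == "chr2"]
        assert abs(np.mean(unlinked)) < 0.05

    def test_scenario_validation(self):
        genome = GenomeInfo(chromosomes=(("chr1", 1000),))
        with pytest.raises(ValueError):
            SyntheticScenario(genome=genome, causal=("chr1", 2000),
                              designs=(BulkDesign(10, 2),))
        with pytest.raises(ValueError):
            SyntheticScenario(genome=genome, causal=("chr1", 500),
                              designs=(BulkDesign(10, 2),), error_rate=0.5)

    def test_error_rate_pulls_index_off_fixation(self):
        sc = default_scenario(seed=4, n_variants=50, error_rate=0.05,
                              depth_mean=5000)
        text, _ = generate_vcf(sc)
        line = next(l for l in text.splitlines() if l.startswith("chr1\t5000000\t"))
        ref_d, alt_d = map(int, line.split("\t")[-1].split(":")[1].split(","))
        assert alt_d / (ref_d + alt_d) == pytest.approx(0.95, abs=0.02)
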