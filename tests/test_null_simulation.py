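import io
import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import binom

from bsascan.bsa_stats import IndexedVariant
from bsascan.null_simulation import (BulkDesign, CITable, CorrectionInput,
                                     SimulationConfigError, build_ci_table,
                                     classify, corrected_levels,
                                     effective_tests, sample_bulk_freq,
                                     segregation_probs,
                                     simulate_null_statistic)

F2_N20 = BulkDesign(n_individuals=20, generation=2)


class TestSegregationProbs:
    def test_f2_mendelian_ratios(self):
        m = segregation_probs(2)
        assert (m.p_hom_parent, m.p_het, m.p_hom_nonparent) == (0.25, 0.5, 0.25)

    def test_f6_heterozygosity_from_halving_recurrence(self):
        # h_2 = 0.5, halved each selfing: h_6 = 0.5 / 2**4
        assert segregation_probs(6).p_het == 0.03125
        assert segregation_probs(6).p_hom_parent == (1 - 0.03125) / 2

    def test_inbred_limit(self):
        m = segregation_probs(60)
        assert m.p_het == pytest.approx(0.0, abs=1e-15)
        assert m.p_hom_parent == pytest.approx(0.5)

    def test_probs_sum_to_one_any_generation(self):
        for k in range(2, 12):
            m = segregation_probs(k)
            assert m.p_hom_parent + m.p_het + m.p_hom_nonparent == pytest.approx(1.0)

    def test_pre_f2_rejected(self):
        with pytest.raises(SimulationConfigError):
            segregation_probs(1)


class TestSampleBulkFreq:
    def test_single_inbred_individual_is_fixed(self):
        rng = np.random.default_rng(0)
        draws = sample_bulk_freq(BulkDesign(1, 40), rng, size=2000)
        assert set(np.unique(draws)) <= {0.0, 1.0}

    def test_mean_is_half_for_any_generation(self):
        rng = np.random.default_rng(1)
        for k in (2, 6):
            draws = sample_bulk_freq(BulkDesign(20, k), rng, size=50_000)
            se = draws.std() / math.sqrt(draws.size)
            assert abs(draws.mean() - 0.5) < 3 * se

    def test_variance_matches_closed_form_f2(self):
        # per-individual allele fraction in {0, .5, 1} w.p. (.25, .5, .25):
        # Var = .25*.25 + .5*0 + .25*.25 = 0.125; bulk of n divides by n
        rng = np.random.default_rng(2)
        draws = sample_bulk_freq(F2_N20, rng, size=200_000)
        assert draws.var() == pytest.approx(0.125 / 20, rel=0.03)


def enumerate_null(depth, n, generation=2):
    """Independent brute-force oracle: genotype tuples x binomial reads."""
    h = 0.5 ** (generation - 1)
    probs = [(1 - h) / 2, h, (1 - h) / 2]
    dist = {}
    for combo in product(range(3), repeat=n):
        pg = math.prod(probs[g] for g in combo)
        f = sum(combo) / (2 * n)
        for k in range(depth + 1):
            dist[k / depth] = dist.get(k / depth, 0.0) + pg * binom.pmf(k, depth, f)
    return dist


class TestSimulateNullStatistic:
    def test_depth1_single_f2_individual_half_half(self):
        # E over genotype classes {0,.5,1} w.p. (.25,.5,.25): P(read alt)=.5
        rng = np.random.default_rng(3)
        sims = simulate_null_statistic(1, BulkDesign(1, 2), 100_000, rng)
        assert set(np.unique(sims)) == {0.0, 1.0}
        assert sims.mean() == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(100_000))

    def test_two_bulk_statistic_symmetric_about_zero(self):
        rng = np.random.default_rng(4)
        sims = simulate_null_statistic((80, 120), (F2_N20, BulkDesign(30, 6)),
                                       100_000, rng)
        se = sims.std() / math.sqrt(sims.size)
        assert abs(sims.mean()) < 3 * se
        assert sims.min() >= -1.0 and sims.max() <= 1.0

    def test_matches_enumeration_n2_depth2(self):
        rng = np.random.default_rng(5)
        sims = simulate_null_statistic(2, BulkDesign(2, 2), 100_000, rng)
        exact = enumerate_null(2, 2)
        vals, counts = np.unique(sims, return_counts=True)
        emp = dict(zip(vals.tolist(), (counts / sims.size).tolist()))
        tv = 0.5 * sum(abs(emp.get(v, 0.0) - p) for v in set(exact) | set(emp)
                       for p in [exact.get(v, 0.0)])
        assert tv < 0.01

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationConfigError):
            simulate_null_statistic(0, F2_N20, 10, rng)
        with pytest.raises(SimulationConfigError):
            simulate_null_statistic(10, F2_N20, 0, rng)


class TestBuildCITable:
    def test_level_nesting_and_range(self):
        table = build_ci_table([10, 50, 200], F2_N20, levels=(0.95, 0.99),
                               reps=20_000, seed=7)
        for key, per_level in table.bounds.items():
            lo95, hi95 = per_level[0.95]
            lo99, hi99 = per_level[0.99]
            assert lo99 <= lo95 <= hi95 <= hi99
            assert 0.0 <= lo99 and hi99 <= 1.0

    def test_bounds_narrow_with_depth(self):
        # read-sampling variance shrinks like 1/depth
        table = build_ci_table([10, 50, 200], F2_N20, reps=20_000, seed=8)
        widths = [table.bounds[(d,)][0.95][1] - table.bounds[(d,)][0.95][0]
                  for d in (10, 50, 200)]
        assert widths[0] > widths[1] > widths[2]

    def test_two_bulk_bounds_in_signed_range(self):
        table = build_ci_table([(30, 60)], (F2_N20, F2_N20), reps=20_000, seed=9)
        lo, hi = table.bounds[(30, 60)][0.95]
        assert -1.0 <= lo < 0 < hi <= 1.0

    def test_deterministic_and_order_independent(self):
        a = build_ci_table([10, 50], F2_N20, reps=5_000, seed=1)
        b = build_ci_table([50, 10, 50], F2_N20, reps=5_000, seed=1)
        assert a.bounds == b.bounds

    def test_reps_too_small_for_quantile(self):
        with pytest.raises(SimulationConfigError):
            build_ci_table([10], F2_N20, levels=(0.999,), reps=100)

    def test_tsv_round_figures(self):
        table = build_ci_table([10], F2_N20, reps=5_000, seed=1)
        sink = io.StringIO()
        table.to_tsv(sink)
        lines = sink.getvalue().splitlines()
        assert lines[1].split("\t") == ["DEPTH", "LEVEL", "LOWER", "UPPER"]
        assert len(lines) == 2 + 2  # comment + header + one depth x two levels


class TestCorrectedLevels:
    def test_m_equals_one_is_identity(self):
        corr = CorrectionInput(n_chromosomes=1, genome_size_bp=10**6, total_cm=50.0)
        assert effective_tests(corr) == 1
        assert corrected_levels((0.95, 0.99), corr) == (0.95, 0.99)

    def test_sidak_formula_m2(self):
        corr = CorrectionInput(n_chromosomes=2, genome_size_bp=10**6, total_cm=100.0)
        (lv,) = corrected_levels((0.95,), corr)
        assert 1 - lv == pytest.approx(1 - 0.95 ** 0.5, abs=1e-10)
        assert 1 - lv == pytest.approx(0.02532, abs=5e-6)

    def test_adjusted_alpha_strictly_decreasing_in_m(self):
        alphas = []
        for cm in (50, 150, 400, 1500):
            corr = CorrectionInput(1, 10**6, float(cm))
            (lv,) = corrected_levels((0.95,), corr)
            alphas.append(1 - lv)
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_unavailable_without_inputs(self):
        with pytest.raises(SimulationConfigError):
            corrected_levels((0.95,), None)
        with pytest.raises(SimulationConfigError):
            CorrectionInput(0, 10**6, 100.0)


def _iv(stat, depth=20):
    one_bulk = not isinstance(stat, tuple)
    if one_bulk:
        return IndexedVariant(chrom="c", pos=1, ref="A", alt="G",
                              depths=(depth,), indices=(stat,))
    i1, i2 = stat
    return IndexedVariant(chrom="c", pos=1, ref="A", alt="G",
                          depths=(depth, depth), indices=(i1, i2), delta=i1 - i2)


class TestClassify:
    def _table(self):
        t = CITable(mode="one-bulk", designs=BulkDesign(20, 2), levels=(0.95,),
                    reps=100, seed=0, depth_cap=100)
        t.bounds[(20,)] = {0.95: (0.21, 0.79)}
        t.bounds[(100,)] = {0.95: (0.3, 0.7)}
        return t

    def test_outside_bounds_is_flagged(self):
        flags = classify(_iv(1.0), self._table())
        assert flags[0.95] is True

    def test_exactly_on_bound_is_not_flagged(self):
        assert classify(_iv(0.79), self._table())[0.95] is False
        assert classify(_iv(0.21), self._table())[0.95] is False

    def test_center_never_flagged_with_simulated_tables(self):
        table = build_ci_table([10, 100], F2_N20, reps=10_000, seed=2)
        for d in (10, 100):
            assert classify(_iv(0.5, depth=d), table) == {0.95: False, 0.99: False}

    def test_depth_beyond_cap_uses_capped_bounds(self):
        flags = classify(_iv(0.99, depth=4000), self._table())
        assert flags[0.95] is True  # served by the depth-100 (cap) entry


def test_null_coverage_at_both_levels():
    """Variants generated under the null are flagged at ~alpha by an
    independently seeded CI table."""
    table = build_ci_table([100], F2_N20, levels=(0.95, 0.99), reps=100_000, seed=11)
    rng = np.random.default_rng(202)
    p = sample_bulk_freq(F2_N20, rng, size=20_000)
    stats = rng.binomial(100, p) / 100
    for level, lo_band, hi_band in ((0.95, 0.04, 0.06), (0.99, 0.005, 0.015)):
        lo, hi = table.bounds[(100,)][level]
        frac = float(np.mean((stats < lo) | (stats > hi)))
        assert lo_band <= frac <= hi_band
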