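"""ANOVA, Tukey HSD, t-tests and OLS against hand values and scipy references."""

import numpy as np
import pytest
from scipy import stats as sps

from hemegate.stats import (
    GroupedSamples,
    one_way_anova,
    simple_linear_regression,
    tukey_pairwise,
    unpaired_t_test,
)


def _gs(*groups):
    return GroupedSamples(groups=[(f"g{i}", np.asarray(g, float)) for i, g in enumerate(groups)])


class TestOneWayANOVA:
    def test_identical_groups_f_zero_p_one(self):
        res = one_way_anova(_gs([1, 2, 3], [1, 2, 3]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_groups(self):
        # groups {1,2,3} and {2,3,4}: SSB = 1.5, SSW = 4, df = (1, 4), F = 1.5
        res = one_way_anova(_gs([1, 2, 3], [2, 3, 4]))
        assert res.statistic == pytest.approx(1.5, abs=1e-12)
        assert res.df == (1.0, 4.0)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.normal(), 1, size=rng.integers(3, 12))
                      for _ in range(rng.integers(2, 5))]
            res = one_way_anova(_gs(*groups))
            ref = sps.f_oneway(*groups)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        f = one_way_anova(_gs(a, b)).statistic
        t = unpaired_t_test(a, b).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(_gs([1.0, 1.0], [1.0, 1.0]))

    def test_null_p_values_uniform(self, rng):
        # permuted labels on null data: p ~ U(0,1)
        pvals = []
        for _ in range(500):
            data = rng.normal(0, 1, 30)
            groups = np.split(rng.permutation(data), 3)
            pvals.append(one_way_anova(_gs(*groups)).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestTukey:
    def test_identical_groups_all_p_one(self):
        res = tukey_pairwise(_gs([1, 2, 3], [1, 2, 3], [1, 2, 3]))
        for pw in res.pairwise:
            assert pw.adjusted_p == pytest.approx(1.0, abs=1e-10)

    def test_two_groups_reduces_to_t_test(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 9)
        tukey_p = tukey_pairwise(_gs(a, b)).pairwise[0].adjusted_p
        t_p = unpaired_t_test(a, b).p_value
        assert tukey_p == pytest.approx(t_p, rel=1e-6)

    def test_matches_scipy_tukey_hsd(self, rng):
        for _ in range(10):
            groups = [rng.normal(rng.normal(), 1, size=rng.integers(4, 10))
                      for _ in range(rng.integers(3, 5))]
            res = tukey_pairwise(_gs(*groups))
            ref = sps.tukey_hsd(*groups)
            for pw in res.pairwise:
                i = int(pw.pair[0][1:])
                j = int(pw.pair[1][1:])
                assert pw.adjusted_p == pytest.approx(ref.pvalue[i, j], rel=1e-8, abs=1e-10)

    def test_matches_statsmodels_tukeyhsd(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.2)]
        res = tukey_pairwise(_gs(*groups))
        data = np.concatenate(groups)
        labels = np.repeat([f"g{i}" for i in range(3)], [len(g) for g in groups])
        ref = pairwise_tukeyhsd(data, labels)
        ref_p = {(a, b): p for (a, b), p in zip(
            [tuple(row[:2]) for row in ref.summary().data[1:]], ref.pvalues)}
        for pw in res.pairwise:
            assert pw.adjusted_p == pytest.approx(ref_p[pw.pair], abs=1e-6)

    def test_adjusted_p_at_least_unadjusted(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.4, 1.0)]
        res = tukey_pairwise(_gs(*groups))
        values = {f"g{i}": g for i, g in enumerate(groups)}
        for pw in res.pairwise:
            raw = unpaired_t_test(values[pw.pair[0]], values[pw.pair[1]]).p_value
            assert pw.adjusted_p >= raw - 1e-10

    def test_shifted_group_dominates_rejections(self, rng):
        rejections = {"g0": 0, "g1": 0, "g2": 0}
        for _ in range(50):
            groups = [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(2.0, 1, 8)]
            for pw in tukey_pairwise(_gs(*groups)).pairwise:
                if pw.adjusted_p < 0.05:
                    for g in pw.pair:
                        rejections[g] += 1
        assert rejections["g2"] > rejections["g0"]
        assert rejections["g2"] > rejections["g1"]


class TestTTest:
    def test_identical_samples(self):
        res = unpaired_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # a=(1,2,3), b=(2,4,6): pooled var 2.5, t = -2/sqrt(5/3), df 4
        res = unpaired_t_test([1.0, 2, 3], [2.0, 4, 6])
        assert res.statistic == pytest.approx(-2.0 / np.sqrt(5.0 / 3.0), rel=1e-12)
        assert res.df == (4.0,)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 9)
        r1, r2 = unpaired_t_test(a, b), unpaired_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    @pytest.mark.parametrize("welch", [False, True])
    def test_matches_scipy(self, rng, welch):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(4, 15))
            b = rng.normal(0.3, 2, rng.integers(4, 15))
            res = unpaired_t_test(a, b, welch=welch)
            ref = sps.ttest_ind(a, b, equal_var=not welch)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = simple_linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        res = simple_linear_regression(np.arange(5.0), np.full(5, 3.0))
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            simple_linear_regression(np.full(5, 2.0), np.arange(5.0))

    def test_matches_scipy_linregress(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            y = 0.7 * x + rng.normal(0, 0.5, 30)
            res = simple_linear_regression(x, y)
            ref = sps.linregress(x, y)
            assert res.slope == pytest.approx(ref.slope, rel=1e-10)
            assert res.intercept == pytest.approx(ref.intercept, rel=1e-10, abs=1e-12)
            assert res.r_squared == pytest.approx(ref.rvalue**2, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_noisy_planted_slope_within_3_se(self, rng):
        x = np.linspace(0, 100, 200)
        y = 0.001 * x + rng.normal(0, 0.01, 200)
        res = simple_linear_regression(x, y)
        assert abs(res.slope - 0.001) <= 3 * res.slope_se
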