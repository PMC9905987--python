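"""Test-kernel correctness: hand-computed examples, library cross-checks,
invariances, and small-sample enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import phacksim as ph
from phacksim.rngdata import DegenerateDataError, InvalidArgumentError


def _rand_groups(seed, n1=12, n2=15):
    g = np.random.default_rng(seed)
    return g.standard_normal(n1), g.standard_normal(n2)


class TestStudentT:
    def test_identical_groups(self):
        r = ph.student_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0 and r.p == 1 and r.effect_size == 0

    def test_hand_computed_example(self):
        r = ph.student_t([1, 2, 3], [3, 4, 5])
        assert r.effect_size == pytest.approx(-2.0)
        assert r.statistic == pytest.approx(-2 * np.sqrt(3 / 2))
        assert r.df == 4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy(self, seed):
        g1, g2 = _rand_groups(seed)
        r = ph.student_t(g1, g2)
        sp = stats.ttest_ind(g1, g2)
        assert r.statistic == pytest.approx(sp.statistic)
        assert r.p == pytest.approx(sp.pvalue)

    def test_null_pvalues_uniform(self):
        ps = [ph.student_t(*_rand_groups(s, 30, 30)).p for s in range(1000)]
        assert stats.kstest(ps, "uniform").statistic < 0.05

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
    def test_location_scale_invariance(self, shift, scale):
        g1, g2 = _rand_groups(3)
        base = ph.student_t(g1, g2)
        moved = ph.student_t(scale * (g1 + shift), scale * (g2 + shift))
        assert moved.p == pytest.approx(base.p, rel=1e-9)
        assert moved.effect_size == pytest.approx(base.effect_size, rel=1e-9)

    def test_group_swap_flips_sign_only(self):
        g1, g2 = _rand_groups(4)
        a, b = ph.student_t(g1, g2), ph.student_t(g2, g1)
        assert a.p == pytest.approx(b.p)
        assert a.effect_size == pytest.approx(-b.effect_size)

    def test_degenerate_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            ph.student_t([1, 1, 1], [2, 2, 2])


class TestWelchAndYuen:
    @pytest.mark.parametrize("seed", [0, 5])
    def test_welch_matches_scipy(self, seed):
        g1, g2 = _rand_groups(seed)
        r = ph.welch_t(g1, g2)
        sp = stats.ttest_ind(g1, g2, equal_var=False)
        assert r.statistic == pytest.approx(sp.statistic)
        assert r.p == pytest.approx(sp.pvalue)

    def test_yuen_zero_trim_is_welch(self):
        g1, g2 = _rand_groups(6)
        y, w = ph.yuen_t(g1, g2, 0.0), ph.welch_t(g1, g2)
        assert y.statistic == pytest.approx(w.statistic)
        assert y.p == pytest.approx(w.p)

    @pytest.mark.parametrize("trim", [0.1, 0.2])
    def test_yuen_matches_scipy_trimmed(self, trim):
        g1, g2 = _rand_groups(7, 20, 25)
        y = ph.yuen_t(g1, g2, trim)
        sp = stats.ttest_ind(g1, g2, equal_var=False, trim=trim)
        assert y.statistic == pytest.approx(sp.statistic)
        assert y.p == pytest.approx(sp.pvalue)

    def test_over_trimming_rejected(self):
        with pytest.raises((DegenerateDataError, InvalidArgumentError)):
            ph.yuen_t([1.0, 2, 3], [4.0, 5, 6], 0.45)


def _exact_ranksum_p(g1, g2):
    """Exhaustive enumeration of the two-sided rank-sum null distribution."""
    pooled = np.concatenate([g1, g2])
    ranks = stats.rankdata(pooled)
    n1, n = len(g1), len(pooled)
    observed = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2
    dev = abs(observed - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        count += abs(w - mean_w) >= dev - 1e-9
    return count / total


class TestWilcoxon:
    def test_matches_scipy_asymptotic(self):
        g1, g2 = _rand_groups(8, 30, 30)
        r = ph.wilcoxon_rank_sum(g1, g2)
        sp = stats.mannwhitneyu(g1, g2, method="asymptotic", use_continuity=True)
        assert r.p == pytest.approx(sp.pvalue)

    def test_extreme_separation_small_sample(self):
        r = ph.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        exact = _exact_ranksum_p([1, 2, 3], [4, 5, 6])
        assert exact == pytest.approx(0.1)
        # normal approximation is close to, and more conservative than, 2/20
        assert abs(r.p - exact) < 0.03

    @pytest.mark.parametrize("seed", [0, 1])
    def test_close_to_enumeration_at_n8(self, seed):
        g1, g2 = _rand_groups(seed, 8, 8)
        r = ph.wilcoxon_rank_sum(g1, g2)
        assert abs(r.p - _exact_ranksum_p(g1, g2)) < 0.02

    def test_all_tied_rejected(self):
        with pytest.raises(DegenerateDataError):
            ph.wilcoxon_rank_sum([1, 1, 1], [1, 1, 1])


class TestAnova:
    def test_two_groups_equal_t_squared(self):
        g1, g2 = _rand_groups(9)
        f = ph.anova_f([g1, g2])
        t = ph.student_t(g1, g2)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.p == pytest.approx(t.p)

    def test_matches_scipy(self):
        g = np.random.default_rng(10)
        groups = [g.standard_normal(12) for _ in range(3)]
        r = ph.anova_f(groups)
        sp = stats.f_oneway(*groups)
        assert r.statistic == pytest.approx(sp.statistic)
        assert r.p == pytest.approx(sp.pvalue)

    def test_identical_groups(self):
        r = ph.anova_f([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == 0 and r.p == 1


class TestOlsSlope:
    def test_hand_computed_example(self):
        r = ph.ols_slope([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.effect_size == pytest.approx(0.64)
        assert r.statistic == pytest.approx(np.sqrt(0.64 * 2 / 0.36))

    def test_perfect_fit(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r = ph.ols_slope(x, x)
        assert r.effect_size == pytest.approx(1.0) and r.p == 0

    def test_orthogonal(self):
        x = np.array([1.0, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1])
        r = ph.ols_slope(x, y)
        assert r.p == pytest.approx(1.0) and r.effect_size == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_scipy_linregress(self, seed):
        g = np.random.default_rng(seed)
        x, y = g.standard_normal(40), g.standard_normal(40)
        r = ph.ols_slope(x, y)
        sp = stats.linregress(x, y)
        assert r.p == pytest.approx(sp.pvalue)
        assert r.effect_size == pytest.approx(sp.rvalue**2)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDataError):
            ph.ols_slope([1, 1, 1, 1], [1, 2, 3, 4])


class TestAncova:
    def test_no_covariates_equals_binary_ols_t(self):
        g1, g2 = _rand_groups(11, 20, 20)
        y = np.concatenate([g1, g2])
        group = np.repeat([0.0, 1.0], 20)
        a = ph.ancova_group_test(y, group)
        t = ph.student_t(g1, g2)
        assert a.p == pytest.approx(t.p)
        assert abs(a.statistic) == pytest.approx(abs(t.statistic))

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        g = np.random.default_rng(12)
        n = 60
        y = g.standard_normal(n)
        group = (g.random(n) < 0.5).astype(float)
        z = g.standard_normal((n, 3))
        r = ph.ancova_group_test(y, group, z)
        X = sm.add_constant(np.column_stack([group, z]))
        fit = sm.OLS(y, X).fit()
        assert r.statistic == pytest.approx(fit.tvalues[1])
        assert r.p == pytest.approx(fit.pvalues[1])

    def test_rank_deficiency_rejected(self):
        y = np.arange(10.0)
        group = np.repeat([0.0, 1.0], 5)
        with pytest.raises(DegenerateDataError):
            ph.ancova_group_test(y, group, np.column_stack([group, group]))


class TestShapiro:
    def test_null_calibration(self):
        g = np.random.default_rng(13)
        rej = sum(ph.shapiro_wilk_p(g.standard_normal(30)) < 0.05 for _ in range(1000))
        assert abs(rej / 1000 - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_skewed_residuals_rejected_often(self):
        g = np.random.default_rng(14)
        rej = sum(ph.shapiro_wilk_p(1.0 / (g.standard_normal(30) + 5)) < 0.05
                  for _ in range(300))
        # reciprocal of a shifted normal is noticeably skewed only mildly; use a
        # clearly non-normal case instead
        rej2 = sum(ph.shapiro_wilk_p(np.exp(g.standard_normal(30))) < 0.05
                   for _ in range(300))
        assert rej2 / 300 > 0.5 and rej2 >= rej

    def test_bounds_and_degenerate(self):
        with pytest.raises(InvalidArgumentError):
            ph.shapiro_wilk_p([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            ph.shapiro_wilk_p(np.ones(10))


class TestCronbach:
    def test_parallel_items(self):
        col = np.random.default_rng(15).standard_normal(50)
        items = np.column_stack([col] * 4)
        assert ph.cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        items = np.random.default_rng(16).standard_normal((20_000, 4))
        assert abs(ph.cronbach_alpha(items)) < 0.05

    def test_compound_symmetric_closed_form(self):
        k, r = 6, 0.4
        items = ph.mvn_compound_symmetry(20_000, k, r, ph.spawn_stream(17, [0]))
        assert ph.cronbach_alpha(items) == pytest.approx(k * r / (1 + (k - 1) * r), abs=0.02)

    def test_alpha_if_deleted_matches_manual(self):
        items = np.random.default_rng(18).standard_normal((100, 5))
        aid = ph.alpha_if_deleted(items)
        for j in range(5):
            manual = ph.cronbach_alpha(np.delete(items, j, axis=1))
            assert aid[j] == pytest.approx(manual)

    def test_single_item_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ph.cronbach_alpha(np.ones((10, 1)))
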