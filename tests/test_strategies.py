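"""Candidate-count contracts, closed-form anchors and behavioural properties
of the twelve p-hacking strategies."""

import numpy as np
import pytest

import phacksim as ph
from phacksim.rngdata import DegenerateDataError, InvalidArgumentError

from conftest import binom_3se, mc_fp


class TestCandidateCounts:
    def test_s1_one_test_per_dv(self, rng):
        b = ph.gen_two_group(30, k_dv=7, rng=rng)
        run = ph.s1_selective_dv(b)
        assert len(run.candidates) == 7
        assert run.candidates[0].test_label == "student_t"

    def test_s2_ttest_uses_fixed_control(self, rng):
        b = ph.gen_two_group(30, k_dv=4, rng=rng)
        assert len(ph.s2_selective_iv(b, "ttest").candidates) == 4

    def test_s3_two_peeks_when_step_exceeds_range(self):
        run = ph.s3_optional_stopping(30, 50, 100, rng=ph.spawn_stream(0, [0]))
        assert len(run.candidates) <= 2

    def test_s3_single_peek_when_min_equals_max(self):
        run = ph.s3_optional_stopping(30, 30, 5, rng=ph.spawn_stream(0, [1]))
        assert len(run.candidates) == 1

    def test_s3_stops_at_first_significant_peek(self):
        for it in range(300):
            run = ph.s3_optional_stopping(5, 50, 5, rng=ph.spawn_stream(1, [it]))
            ps = run.pvalues()
            assert (ps[:-1] >= 0.05).all()  # only the last candidate may be significant

    def test_s5_three_covariates_give_five_extra_tests(self, rng):
        b = ph.gen_two_group(30, k_cov=3, r_z=0.3, r_zy=0.3, rng=rng)
        run = ph.s5_covariates(b)
        assert len(run.candidates) == 6
        assert run.candidates[0].test_label == "student_t"

    def test_s6_two_candidates_per_deletion(self, rng):
        b = ph.gen_regression(40, k_items=5, r_items=0.3, rng=rng)
        assert len(ph.s6_scale_redefinition(b, m_max=0).candidates) == 1
        assert len(ph.s6_scale_redefinition(b, m_max=3).candidates) == 7
        # cannot delete below 2 remaining items
        assert len(ph.s6_scale_redefinition(b, m_max=10).candidates) == 7

    def test_s7_ungated_has_ten_candidates(self, rng):
        b = ph.gen_regression(30, rng=rng)
        run = ph.s7_transformation(b)
        assert len(run.candidates) + run.skipped == 10

    def test_s8_four_candidates(self, rng):
        b = ph.gen_regression(60, rng=rng)
        assert len(ph.s8_discretization(b).candidates) == 4

    def test_s9_seven_candidates(self, rng):
        b = ph.gen_two_group(30, rng=rng)
        run = ph.s9_alternative_tests(b)
        assert len(run.candidates) == 7
        labels = [c.test_label for c in run.candidates]
        assert labels[:3] == ["student_t", "welch_t", "wilcoxon"]

    def test_s10_at_most_k_plus_one(self):
        run = ph.simulate_once("s10", {"n": 50, "rho": 0.2, "k_methods": 10},
                               0.05, ph.spawn_stream(2, [0]))
        assert len(run.candidates) <= 11
        assert run.candidates[0].test_label == "listwise_planned"

    def test_s11_one_plus_two_per_grouping(self, rng):
        b = ph.gen_two_group(100, k_groups=3, rng=rng)
        run = ph.s11_subgroups(b)
        assert len(run.candidates) + run.skipped == 7

    def test_s4_no_flags_leaves_only_planned_test(self):
        b = ph.DatasetBundle(n=5, x=np.array([-1.0, -0.5, 0.0, 0.5, 1.0]),
                             y=np.array([-1.0, 0.5, 0.0, -0.5, 1.0]))
        run = ph.s4_outlier_exclusion(b, 12)
        assert len(run.candidates) == 1

    def test_s4_candidates_shrink_but_stay_testable(self):
        run = ph.simulate_once("s4", {"n": 50, "k_methods": 12}, 0.05,
                               ph.spawn_stream(3, [0]))
        for c in run.candidates[1:]:
            assert 4 <= c.n_used < 50


class TestRunSemantics:
    def test_success_is_min_p_rule(self, rng):
        b = ph.gen_two_group(30, k_dv=5, rng=rng)
        run = ph.s1_selective_dv(b, alpha=0.5)
        assert run.success == (run.min_p < 0.5)

    def test_missing_components_rejected(self, rng):
        b = ph.gen_regression(30, rng=rng)
        with pytest.raises(InvalidArgumentError):
            ph.s1_selective_dv(b)

    def test_constant_predictor_is_error_not_success(self):
        b = ph.DatasetBundle(n=10, x=np.ones(10), y=np.arange(10.0))
        with pytest.raises(DegenerateDataError):
            ph.s8_discretization(b)

    def test_perfectly_correlated_dvs_share_pvalue(self, rng):
        b = ph.gen_two_group(30, k_dv=5, r_dv=1.0, rng=rng)
        ps = ph.s1_selective_dv(b).pvalues()
        assert np.allclose(ps, ps[0])

    def test_s6_identical_items_give_identical_candidates(self):
        g = np.random.default_rng(4)
        col = g.standard_normal(40)
        b = ph.DatasetBundle(n=40, items=np.column_stack([col] * 5),
                             y=g.standard_normal(40))
        ps = ph.s6_scale_redefinition(b, m_max=2).pvalues()
        assert np.allclose(ps, ps[0])

    def test_s10_no_missingness_all_candidates_identical(self):
        run = ph.simulate_once("s10", {"n": 50, "rho": 0.0, "k_methods": 10},
                               0.05, ph.spawn_stream(5, [0]))
        ps = run.pvalues()
        assert np.allclose(ps, ps[0])

    def test_s11_skips_undersized_subgroups(self):
        g = np.random.default_rng(6)
        b = ph.DatasetBundle(n=20, group1=g.standard_normal((20, 1)),
                             group2=g.standard_normal((20, 1)),
                             grouping_vars=np.zeros((40, 1), dtype=int))
        run = ph.s11_subgroups(b)
        assert len(run.candidates) == 2  # full sample + the all-zero level
        assert run.skipped == 1

    def test_s9_identical_groups_never_succeed(self):
        vals = np.arange(10.0)
        b = ph.DatasetBundle(n=10, group1=vals.reshape(-1, 1), group2=vals.reshape(-1, 1))
        run = ph.s9_alternative_tests(b)
        assert not run.success
        assert all(c.p > 0.9 for c in run.candidates)


class TestIncorrectRounding:
    def test_level_equal_alpha_is_identity(self):
        for p in (0.001, 0.049, 0.05, 0.2, 1.0):
            sig, rep = ph.s12_incorrect_rounding(p, 0.05, 0.05)
            assert sig == (p < 0.05) and rep == p

    def test_rounding_band_reports_alpha(self):
        sig, rep = ph.s12_incorrect_rounding(0.0505, 0.051, 0.05)
        assert sig and rep == 0.05
        sig, rep = ph.s12_incorrect_rounding(0.055, 0.06, 0.05)
        assert sig and rep == 0.05
        sig, rep = ph.s12_incorrect_rounding(0.0555, 0.051, 0.05)
        assert not sig and rep == 0.0555

    def test_analytic_effective_rate(self):
        """P(success) = level exactly for uniform p, by the rule's definition."""
        grid = np.linspace(0.0005, 0.9995, 1000)  # midpoint grid of U(0,1)
        for level in (0.051, 0.06):
            rate = np.mean([ph.s12_incorrect_rounding(p, level, 0.05)[0] for p in grid])
            assert rate == pytest.approx(level, abs=0.0006)


class TestClosedFormAnchors:
    def test_s1_independent_dvs_match_alpha_accumulation(self):
        fp = mc_fp("s1", {"n": 30, "k_dv": 10, "r_dv": 0.0}, 2000, seed=11)
        assert abs(fp - (1 - 0.95**10)) < binom_3se(0.401, 2000)

    def test_s1_single_dv_is_calibrated(self):
        fp = mc_fp("s1", {"n": 30, "k_dv": 1}, 2000, seed=12)
        assert abs(fp - 0.05) < binom_3se(0.05, 2000)

    def test_s2_regression_matches_alpha_accumulation(self):
        fp = mc_fp("s2", {"n": 30, "k_iv": 10, "r_iv": 0.0, "design": "regression"},
                   2000, seed=13)
        assert abs(fp - (1 - 0.95**10)) < binom_3se(0.401, 2000)

    def test_s2_ttest_shared_control_dampens_inflation(self):
        fp = mc_fp("s2", {"n": 30, "k_iv": 10, "r_iv": 0.0, "design": "ttest"},
                   2000, seed=14)
        assert 0.05 + binom_3se(0.05, 2000) < fp < (1 - 0.95**10) - binom_3se(0.4, 2000)

    def test_success_rate_bounded_by_independence(self):
        # m candidates can never exceed 1 - (1-alpha)^m
        fp = mc_fp("s9", {"n": 30}, 1500, seed=15)
        assert 0.05 - binom_3se(0.05, 1500) < fp < 1 - 0.95**7


class TestOrderedSeverity:
    def test_s3_smaller_steps_inflate_more(self):
        fp_fine = mc_fp("s3", {"n_min": 5, "n_max": 100, "step": 1}, 800, seed=16)
        fp_coarse = mc_fp("s3", {"n_min": 5, "n_max": 100, "step": 50}, 800, seed=16, cell=1)
        assert fp_fine > fp_coarse + 0.03

    def test_s5_dv_correlated_covariates_inflate_more(self):
        fp_hi = mc_fp("s5", {"n": 30, "k_cov": 5, "r_z": 0.0, "r_zy": 0.3}, 1200, seed=17)
        fp_lo = mc_fp("s5", {"n": 30, "k_cov": 5, "r_z": 0.0, "r_zy": 0.0}, 1200, seed=17, cell=1)
        assert fp_hi > fp_lo

    def test_s10_more_missingness_inflates_more(self):
        fp_hi = mc_fp("s10", {"n": 100, "rho": 0.2, "k_methods": 10}, 600, seed=18)
        fp_lo = mc_fp("s10", {"n": 100, "rho": 0.05, "k_methods": 10}, 600, seed=18, cell=1)
        assert fp_hi > fp_lo + 0.05

    def test_s7_gate_lowers_severity(self):
        fp_open = mc_fp("s7", {"n": 30}, 1200, seed=19)
        fp_gated = mc_fp("s7", {"n": 30, "gate_on_normality": True}, 1200, seed=19, cell=1)
        assert fp_gated < fp_open - 0.1
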