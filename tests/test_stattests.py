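"""t tests, chi-square, ANCOVA and power against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nutrigrs.stattests import (
    ancova_adjusted_means,
    paired_t,
    paired_t_power,
    paired_t_sample_size,
    pearson_chi_square,
    unpaired_t,
)


def sign_flip_p(diffs: np.ndarray) -> float:
    """Exact two-sided sign-flip permutation p for the paired t statistic."""
    n = diffs.size
    signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    flipped = signs * diffs
    t_all = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(n))
    t_obs = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
    return float(np.mean(np.abs(t_all) >= abs(t_obs) - 1e-12))


class TestPairedT:
    def test_directional_shift_detected(self, rng):
        d = 1.0 + rng.normal(0, 0.01, 12)
        res = paired_t(d)
        assert res.p_value < 1e-10 and res.ci_low > 0

    def test_symmetric_differences_centre_the_ci(self):
        res = paired_t(np.array([-2.0, 2.0, -1.0, 1.0]))
        assert res.estimate == 0.0
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_matches_scipy_ttest_rel(self, rng):
        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0.4, 1, 20)
        res = paired_t(b - a)
        ref = sps.ttest_rel(b, a)
        assert res.t_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_agrees_with_exact_sign_flip_enumeration(self, rng):
        # fixed n=10 vector: the t p-value should track the exact
        # permutation p and agree on rejection at alpha = 0.05
        d = rng.normal(0.8, 1.0, 10)
        res = paired_t(d)
        exact = sign_flip_p(d)
        assert (res.p_value < 0.05) == (exact < 0.05)
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_zero_variance_degenerate(self):
        res = paired_t(np.ones(6))
        assert res.degenerate and np.isnan(res.p_value)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(77)
        draws = rng.normal(0, 1, size=(2000, 15))
        rejections = sum(paired_t(row).p_value < 0.05 for row in draws)
        assert 0.035 <= rejections / 2000 <= 0.065


class TestUnpairedT:
    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = unpaired_t(a, a.copy())
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_and_welch_agree_for_balanced_equal_variance(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        pooled = unpaired_t(a, b, "pooled")
        welch = unpaired_t(a, b, "welch")
        assert pooled.t_statistic == pytest.approx(welch.t_statistic, rel=1e-10)
        assert pooled.p_value == pytest.approx(welch.p_value, rel=0.02)

    def test_matches_scipy_both_modes(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 2, 17)
        for mode, equal_var in (("pooled", True), ("welch", False)):
            res = unpaired_t(a, b, mode)
            ref = sps.ttest_ind(a, b, equal_var=equal_var)
            assert res.t_statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_textbook_hand_computation(self):
        # classic small-sample pooled t: means 5 and 3, pooled SD 1,
        # SE = sqrt(1*(1/3+1/3)), t = 2/0.8165 = 2.449, df = 4
        a = np.array([4.0, 5.0, 6.0])
        b = np.array([2.0, 3.0, 4.0])
        res = unpaired_t(a, b)
        assert res.t_statistic == pytest.approx(2.449, abs=5e-4)
        assert res.df == 4


class TestPearsonChiSquare:
    def test_identical_row_distributions_null(self):
        res = pearson_chi_square([[10, 20, 30], [20, 40, 60]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_printed_genotype_table(self):
        # 2x3 genotype-by-group table from the motivating cohort
        res = pearson_chi_square([[2, 11, 4], [9, 5, 1]])
        assert res.chi2 == pytest.approx(8.412, abs=5e-3)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0149, abs=5e-4)

    def test_perfect_association_closed_form(self):
        res = pearson_chi_square([[10, 0], [0, 10]])
        assert res.chi2 == pytest.approx(20.0, rel=1e-12)
        assert res.p_value == pytest.approx(7.7e-6, rel=0.01)

    def test_two_by_two_closed_form(self, rng):
        a, b, c, d = 7, 3, 4, 11
        res = pearson_chi_square([[a, b], [c, d]])
        n = a + b + c + d
        closed = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.chi2 == pytest.approx(closed, rel=1e-12)

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 30, size=(3, 4))
        base = pearson_chi_square(table)
        shuffled = table[np.argsort(rng.random(3))][:, np.argsort(rng.random(4))]
        res = pearson_chi_square(shuffled)
        assert res.chi2 == pytest.approx(base.chi2, rel=1e-12)

    def test_matches_scipy(self, rng):
        table = rng.integers(1, 25, size=(2, 3))
        res = pearson_chi_square(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert res.chi2 == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_empty_margin_named(self):
        with pytest.raises(ValueError, match="column"):
            pearson_chi_square([[1, 0], [2, 0]])

    def test_yates_only_for_2x2(self):
        with pytest.raises(ValueError, match="2x2"):
            pearson_chi_square(np.ones((2, 3)), yates=True)


class TestAncova:
    def test_zero_covariates_reduce_to_raw_means_and_pooled_t(self, rng):
        y = rng.normal(0, 1, 20)
        g = np.repeat(["a", "b"], 10)
        res = ancova_adjusted_means(y, g)
        assert res.adjusted_means["a"] == pytest.approx(y[:10].mean(), rel=1e-10)
        assert res.adjusted_means["b"] == pytest.approx(y[10:].mean(), rel=1e-10)
        t = unpaired_t(y[:10], y[10:], "pooled")
        assert res.p_value == pytest.approx(t.p_value, rel=1e-10)

    def test_orthogonal_covariate_keeps_raw_means(self, rng):
        g = np.repeat(["a", "b"], 12)
        # covariate symmetric within both groups and unrelated to outcome
        x = np.tile([-1.0, 1.0], 12)
        y = np.where(g == "a", 1.0, 3.0) + rng.normal(0, 0.1, 24)
        res = ancova_adjusted_means(y, g, pd.DataFrame({"x": x}))
        assert res.adjusted_means["a"] == pytest.approx(y[g == "a"].mean(), abs=0.05)
        assert res.adjusted_means["b"] == pytest.approx(y[g == "b"].mean(), abs=0.05)

    def test_six_subject_normal_equations_oracle(self):
        # hand-built instance solved by explicit least squares
        y = np.array([3.0, 4.0, 5.0, 7.0, 8.0, 10.0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 4.0])
        res = ancova_adjusted_means(y, g, pd.DataFrame({"x": x}))
        X = np.column_stack([np.ones(6), (g == "b").astype(float), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        xbar = x.mean()
        assert res.adjusted_means["a"] == pytest.approx(
            beta[0] + beta[2] * xbar, rel=1e-10
        )
        assert res.adjusted_means["b"] == pytest.approx(
            beta[0] + beta[1] + beta[2] * xbar, rel=1e-10
        )
        # residualization oracle for the group p-value
        resid_y = y - X[:, [0, 2]] @ np.linalg.lstsq(X[:, [0, 2]], y, rcond=None)[0]
        ind = X[:, 1]
        resid_g = ind - X[:, [0, 2]] @ np.linalg.lstsq(X[:, [0, 2]], ind, rcond=None)[0]
        beta_g = (resid_g @ resid_y) / (resid_g @ resid_g)
        assert beta_g == pytest.approx(beta[1], rel=1e-10)

    def test_subject_order_invariance(self, rng):
        y = rng.normal(0, 1, 16)
        g = np.repeat(["a", "b"], 8)
        x = rng.normal(0, 1, 16)
        res = ancova_adjusted_means(y, g, pd.DataFrame({"x": x}))
        perm = rng.permutation(16)
        res2 = ancova_adjusted_means(
            y[perm], g[perm], pd.DataFrame({"x": x[perm]})
        )
        assert res2.adjusted_means["a"] == pytest.approx(
            res.adjusted_means["a"], rel=1e-10
        )
        assert res2.p_value == pytest.approx(res.p_value, rel=1e-10)

    def test_constant_covariate_dropped_with_warning(self, rng):
        y = rng.normal(0, 1, 10)
        g = np.repeat(["a", "b"], 5)
        with pytest.warns(UserWarning, match="constant"):
            res = ancova_adjusted_means(
                y, g, pd.DataFrame({"c": np.ones(10)})
            )
        assert res.covariate_names == []

    def test_collinear_covariates_rejected(self, rng):
        y = rng.normal(0, 1, 10)
        g = np.repeat(["a", "b"], 5)
        x = rng.normal(0, 1, 10)
        with pytest.raises(ValueError, match="collinear"):
            ancova_adjusted_means(
                y, g, pd.DataFrame({"x1": x, "x2": 2 * x})
            )


class TestPower:
    def test_study_anchor_sample_size(self):
        # dz = 0.54, alpha 0.05, power 0.80 -> smallest adequate n is 29
        assert paired_t_sample_size(0.54) == 29
        assert paired_t_power(28, 0.54) < 0.80 <= paired_t_power(29, 0.54)

    def test_monotonicity_in_effect_alpha_and_power(self):
        assert paired_t_sample_size(1.08) < paired_t_sample_size(0.54)
        assert paired_t_sample_size(0.54, alpha=0.01) >= paired_t_sample_size(
            0.54, alpha=0.05
        )
        assert paired_t_sample_size(0.54, power=0.9) >= paired_t_sample_size(
            0.54, power=0.8
        )

    def test_floor_case(self):
        assert paired_t_sample_size(1.0, power=0.05) == 2

    def test_unreachable_power_raises(self):
        with pytest.raises(ValueError, match="not reachable"):
            paired_t_sample_size(1e-5, n_max=1000)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            paired_t_sample_size(0.0)
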