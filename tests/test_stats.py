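"""Inference procedures: closed forms, oracles, and published summaries."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from polarland.stats import (
    UseAvailStratum,
    aic_compare,
    anova_from_summary,
    chi2_contingency,
    conditional_logistic,
    linear_regression,
    logistic_two_group,
)
from polarland.synthetic import simulate_use_avail


class TestLogisticTwoGroup:
    @pytest.mark.parametrize(
        "k1,n1,k2,n2,slope,se",
        [
            (16, 80, 14, 36, 0.9, 0.4),  # >7-day land use between periods
            (10, 80, 13, 36, 1.4, 0.5),  # >21-day land use
            (3, 23, 14, 36, 1.4, 0.7),  # >7-day, same-capture-area subsample
        ],
    )
    def test_published_comparisons_reproduce_at_printed_rounding(
        self, k1, n1, k2, n2, slope, se
    ):
        fit = logistic_two_group(k1, n1, k2, n2)
        assert round(fit.coef["slope"], 1) == slope
        assert round(fit.se["slope"], 1) == se

    def test_equal_proportions_give_zero_slope(self):
        fit = logistic_two_group(10, 40, 5, 20)
        assert fit.coef["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_irls_logistic_regression(self):
        k1, n1, k2, n2 = 7, 31, 11, 17
        fit = logistic_two_group(k1, n1, k2, n2)
        y = np.r_[np.ones(k1), np.zeros(n1 - k1), np.ones(k2), np.zeros(n2 - k2)]
        x = np.r_[np.zeros(n1), np.ones(n2)]
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.coef["slope"] == pytest.approx(glm.params[1], abs=1e-8)
        assert fit.se["slope"] == pytest.approx(glm.bse[1], abs=1e-6)

    def test_zero_cell_flagged_as_separation(self):
        fit = logistic_two_group(0, 23, 13, 36)
        assert math.isinf(fit.coef["slope"])
        assert any("separation" in w for w in fit.warnings)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            logistic_two_group(5, 4, 1, 10)

    def test_wald_type_one_error_near_nominal(self):
        """Null rejection rate of the two-group Wald test at alpha = 0.05."""
        rng = np.random.default_rng(2024)
        n1, n2, p = 80, 36, 0.3
        reps = 5000
        k1 = rng.binomial(n1, p, reps)
        k2 = rng.binomial(n2, p, reps)
        rejections = 0
        for a, b in zip(k1, k2):
            if a in (0, n1) or b in (0, n2):
                continue
            fit = logistic_two_group(int(a), n1, int(b), n2)
            rejections += fit.pvalue < 0.05
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07


class TestAnovaFromSummary:
    @pytest.mark.parametrize(
        "m1,sd1,n1,m2,sd2,n2,f,se",
        [
            (32.7, 21.1, 16, 62.6, 20.2, 14, 15.6, 7.6),  # days ashore, >7 d
            (261.4, 22.7, 16, 241.2, 20.2, 14, 6.5, 7.9),  # arrival date
            (287.4, 19.3, 12, 309.7, 6.7, 7, 8.6, 7.6),  # departure date
            (11.1, 15.6, 75, 22.9, 25.7, 35, 8.9, 4.0),  # % locations on land
        ],
    )
    def test_published_comparisons(self, m1, sd1, n1, m2, sd2, n2, f, se):
        fit = anova_from_summary(m1, sd1, n1, m2, sd2, n2)
        assert round(fit.statistic, 1) == f
        assert round(fit.se["diff"], 1) == se
        assert fit.df == (1, n1 + n2 - 2)

    def test_identical_groups(self):
        fit = anova_from_summary(5.0, 2.0, 10, 5.0, 2.0, 10)
        assert fit.statistic == 0.0
        assert fit.pvalue == 1.0

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.3, 9)
        fit = anova_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        t, p = sps.ttest_ind(a, b)
        assert fit.statistic == pytest.approx(t**2, rel=1e-10)
        assert fit.pvalue == pytest.approx(p, rel=1e-10)

    def test_zero_variance_reported_infinite(self):
        fit = anova_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert math.isinf(fit.statistic)


class TestLinearRegression:
    def test_hand_computed_three_points(self):
        # (0,0),(1,1),(2,4): slope 2, intercept -1/3,
        # SS_res = 6/9, SS_tot = 78/9, so R^2 = 12/13
        fit = linear_regression([0, 1, 2], [0, 1, 4])
        assert fit.coef["slope"] == pytest.approx(2.0)
        assert fit.coef["intercept"] == pytest.approx(-1 / 3)
        assert fit.r2 == pytest.approx(12 / 13)

    def test_collinear_points_r2_one(self):
        fit = linear_regression([0, 1, 2, 3], [1, 3, 5, 7])
        assert fit.r2 == pytest.approx(1.0)

    def test_null_slope_coverage(self):
        rng = np.random.default_rng(7)
        inside = 0
        reps = 300
        for _ in range(reps):
            x = rng.uniform(0, 1, 40)
            y = rng.normal(0, 1, 40)
            fit = linear_regression(x, y)
            inside += abs(fit.coef["slope"]) < 3 * fit.se["slope"]
        assert inside / reps >= 0.99 - 0.02

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1, 1, 1], [0, 1, 2])


class TestConditionalLogistic:
    def _grid_oracle(self, strata, grid):
        """Exhaustive 1-d maximization of the exact conditional likelihood."""
        def ll(b):
            out = 0.0
            for s in strata:
                eta = s.covariates[:, 0] * b
                out += eta[np.argmax(s.used)] - np.log(np.exp(eta).sum())
            return out

        vals = [ll(b) for b in grid]
        return grid[int(np.argmax(vals))]

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        strata = []
        for sid in range(3):
            x = rng.normal(0, 1, 4)
            used = np.zeros(4, int)
            used[rng.integers(4)] = 1
            strata.append(UseAvailStratum(str(sid), used, x[:, None]))
        fit = conditional_logistic(strata)
        coarse = np.linspace(-5, 5, 2001)
        b0 = self._grid_oracle(strata, coarse)
        fine = np.linspace(b0 - 0.01, b0 + 0.01, 20001)
        b_star = self._grid_oracle(strata, fine)
        assert abs(fit.coef["x0"] - b_star) < 1e-6

    def test_matches_statsmodels_conditional_logit(self):
        strata = simulate_use_avail(60, beta=0.02, seed=3)
        fit = conditional_logistic(strata)
        y = np.concatenate([s.used for s in strata])
        x = np.concatenate([s.covariates[:, 0] for s in strata])
        groups = np.concatenate(
            [np.full(len(s.used), i) for i, s in enumerate(strata)]
        )
        sm_fit = sm.ConditionalLogit(y, x[:, None], groups=groups).fit(disp=0)
        assert fit.coef["x0"] == pytest.approx(sm_fit.params[0], abs=1e-6)
        assert fit.se["x0"] == pytest.approx(sm_fit.bse[0], rel=1e-3)

    def test_constant_covariate_flagged_unidentifiable(self):
        strata = [
            UseAvailStratum("a", [1, 0], np.array([[3.0], [3.0]])),
            UseAvailStratum("b", [0, 1], np.array([[5.0], [5.0]])),
        ]
        fit = conditional_logistic(strata)
        assert math.isnan(fit.coef["x0"])
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_matched_pairs_reduce_to_logistic_on_differences(self):
        """With 1 used + 1 available per stratum the conditional likelihood
        is an intercept-free logistic regression on covariate differences."""
        rng = np.random.default_rng(5)
        strata = []
        for sid in range(80):
            x = rng.normal(0, 1, 2)
            p = 1 / (1 + np.exp(-(x[0] - x[1])))
            used = np.array([1, 0]) if rng.random() < p else np.array([0, 1])
            strata.append(UseAvailStratum(str(sid), used, x[:, None]))
        fit = conditional_logistic(strata)
        d = np.array(
            [s.covariates[np.argmax(s.used), 0] - s.covariates[np.argmin(s.used), 0]
             for s in strata]
        )
        glm = sm.GLM(
            np.ones(len(d)), d[:, None], family=sm.families.Binomial()
        ).fit()
        assert fit.coef["x0"] == pytest.approx(glm.params[0], abs=1e-6)

    def test_recovery_at_study_effect_scale(self):
        """beta ~ 0.02/day of ice retreat: mean estimate within 10%."""
        estimates = []
        for seed in range(50):
            strata = simulate_use_avail(200, beta=0.02, seed=seed)
            fit = conditional_logistic(strata)
            estimates.append(fit.coef["x0"])
        assert abs(np.mean(estimates) - 0.02) < 0.002


class TestAicCompare:
    def test_identical_fits_all_zero_delta(self):
        from polarland.stats import FitResult

        fits = []
        for lbl in ("a", "b"):
            f = FitResult(label=lbl)
            f.loglik, f.n_params = -10.0, 2
            fits.append(f)
        table = aic_compare(fits)
        assert all(r["delta_aic"] == 0.0 for r in table)

    def test_tie_broken_by_fewer_parameters(self):
        from polarland.stats import FitResult

        f1 = FitResult(label="small")
        f1.loglik, f1.n_params = -10.0, 1
        f2 = FitResult(label="big")
        f2.loglik, f2.n_params = -9.0, 2
        table = aic_compare([f2, f1])
        assert table[0]["label"] == "small"

    def test_retreat_model_wins_when_retreat_drives_use(self):
        """Model selection mirrors the study: when selection follows retreat
        date, the retreat model out-ranks the (correlated) return model."""
        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            strata_r, strata_ret = [], []
            for sid in range(60):
                retreat = rng.uniform(120, 300, 20)
                # return date negatively correlated with retreat, plus noise
                ret = 430.0 - 0.4 * retreat + rng.normal(0, 25, 20)
                w = np.exp(0.02 * (retreat - retreat.mean()))
                used_idx = rng.choice(20, p=w / w.sum())
                used = np.zeros(20, int)
                used[used_idx] = 1
                strata_r.append(UseAvailStratum(str(sid), used, retreat[:, None]))
                strata_ret.append(UseAvailStratum(str(sid), used, ret[:, None]))
            fit_r = conditional_logistic(strata_r, label="retreat")
            fit_ret = conditional_logistic(strata_ret, label="return")
            table = aic_compare([fit_r, fit_ret])
            wins += table[0]["label"] == "retreat"
        assert wins / n_seeds >= 0.8


class TestChi2Contingency:
    def test_proportional_table_zero(self):
        fit = chi2_contingency([[10, 10], [10, 10]])
        assert fit.statistic == pytest.approx(0.0)
        assert fit.pvalue == pytest.approx(1.0)

    def test_direct_formula_2x2(self):
        table = np.array([[20, 5], [5, 20]])
        fit = chi2_contingency(table)
        # Pearson chi2 = N (ad - bc)^2 / (row1 row2 col1 col2)
        a, b, c, d = 20, 5, 5, 20
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert fit.statistic == pytest.approx(expected, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_contingency([[0, 0], [5, 5]])


class TestSlopeIdentityProperty:
    """Closed-form log odds ratio equals the iterative GLM fit for any
    non-degenerate 2x2 counts."""

    def test_property_random_counts(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=30, deadline=None, derandomize=True)
        @given(
            n1=st.integers(3, 60), n2=st.integers(3, 60),
            data=st.data(),
        )
        def check(n1, n2, data):
            k1 = data.draw(st.integers(1, n1 - 1))
            k2 = data.draw(st.integers(1, n2 - 1))
            fit = logistic_two_group(k1, n1, k2, n2)
            expected = math.log((k2 / (n2 - k2)) * (n1 - k1) / k1)
            assert fit.coef["slope"] == pytest.approx(expected, abs=1e-12)
            assert fit.se["slope"] > 0

        check()
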