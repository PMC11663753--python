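import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from rvdys.stats import (chi_square_2x2, compare_groups, cox_fit, describe,
                         pearson_r2, univariate_screen)


def breslow_loglik_bruteforce(beta, time, event, x):
    """Independent loop-based Breslow log partial likelihood."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_matches_bruteforce_maximizer_small_n(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 10).round(2)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        x = rng.normal(0, 1, 10)
        fit = cox_fit(t, e, x, ties="breslow")
        res = minimize_scalar(
            lambda b: -breslow_loglik_bruteforce(b, t, e, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-4)
        assert fit.score_max < 1e-6
        assert fit.converged

    def test_two_group_rate_ratio_recovery(self):
        # exponential data with true hazard ratio 2 between groups
        n = 5000
        rng = np.random.default_rng(9)
        g = rng.binomial(1, 0.5, n)
        T = rng.exponential(1 / (0.1 * 2.0 ** g))
        fit = cox_fit(T, np.ones(n, int), g)
        assert 1.9 <= fit.hazard_ratios[0] <= 2.1

    def test_constant_covariate_error(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 0], np.zeros(4))

    def test_too_few_events_error(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit([1, 2, 3], [1, 0, 0], [0.0, 1.0, 2.0])

    def test_dataset_duplication_invariance_breslow(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(0, 1, n)
        T = rng.exponential(1 / (0.1 * np.exp(0.4 * x)))
        C = rng.exponential(15, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        one = cox_fit(t, e, x, ties="breslow")
        two = cox_fit(np.concatenate([t, t]), np.concatenate([e, e]),
                      np.concatenate([x, x]), ties="breslow")
        assert two.coef[0] == pytest.approx(one.coef[0], abs=1e-7)
        assert two.se[0] == pytest.approx(one.se[0] / np.sqrt(2), rel=1e-6)

    def test_efron_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 400
        x1 = rng.normal(0, 1, n)
        x2 = rng.binomial(1, 0.5, n)
        T = rng.exponential(1 / (0.05 * np.exp(0.5 * x1 - 0.3 * x2)))
        C = rng.exponential(25, n)
        t = np.round(np.minimum(T, C)) + 0.5   # force heavy ties
        e = (T <= C).astype(int)
        fit = cox_fit(t, e, np.column_stack([x1, x2]), ties="efron")
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2}), "t", "e")
        assert np.allclose(fit.coef, cph.params_.values, atol=1e-6)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_separation_flagged_not_raised(self):
        # covariate perfectly orders the event times: monotone likelihood
        x = np.arange(12, dtype=float)
        t = np.arange(1, 13, dtype=float)[::-1]
        e = np.ones(12, int)
        with pytest.warns(RuntimeWarning, match="converge"):
            fit = cox_fit(t, e, x)
        assert not fit.converged

    def test_ci_brackets_hazard_ratio(self):
        rng = np.random.default_rng(11)
        n = 200
        x = rng.normal(0, 1, n)
        T = rng.exponential(1 / (0.1 * np.exp(0.3 * x)))
        fit = cox_fit(T, np.ones(n, int), x)
        assert fit.ci95[0, 0] < fit.hazard_ratios[0] < fit.ci95[0, 1]
        assert fit.hazard_ratios[0] > 0


class TestUnivariateScreen:
    def make_df(self, n=300, seed=3):
        rng = np.random.default_rng(seed)
        age = rng.normal(58, 15, n)
        signal = rng.normal(9, 3, n)
        noise = rng.normal(0, 1, n)
        rate = 5e-4 * np.exp(0.09 * signal + 0.04 * age)
        T = rng.exponential(1 / rate)
        C = rng.uniform(4, 180, n)
        return pd.DataFrame({
            "followup_months": np.minimum(T, C),
            "event": (T <= C).astype(int),
            "age_years": age, "signal": signal, "noise": noise})

    def test_screen_advances_only_small_p(self):
        df = self.make_df()
        out = univariate_screen(df, ["age_years", "signal", "noise"])
        assert out["signal"]["univariate"].p_values[0] < 0.1
        assert out["signal"]["bivariate"] is not None
        assert list(out["signal"]["bivariate"].names) == ["signal",
                                                          "age_years"]
        assert out["noise"]["bivariate"] is None
        # age itself is never age-adjusted
        assert out["age_years"]["bivariate"] is None

    def test_threshold_one_advances_everything(self):
        df = self.make_df()
        out = univariate_screen(df, ["signal", "noise"], threshold=1.0)
        assert out["noise"]["bivariate"] is not None

    def test_threshold_zero_advances_nothing(self):
        df = self.make_df()
        out = univariate_screen(df, ["signal"], threshold=0.0)
        assert out["signal"]["bivariate"] is None


class TestCompareGroups:
    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 40), rng.normal(0.5, 1, 40))
        assert res.test == "t-test"
        assert res.summaries[0]["style"] == "mean_sd"

    def test_skewed_groups_use_mann_whitney(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.lognormal(0, 1, 60),
                             rng.lognormal(0.3, 1, 60))
        assert res.test == "mann-whitney"
        assert res.summaries[0]["style"] == "median_iqr"

    def test_identical_groups_t_test_p_one(self):
        rng = np.random.default_rng(0)
        g = rng.normal(10, 2, 30)
        res = compare_groups(g, g.copy())
        assert res.test == "t-test"
        assert res.p_value == pytest.approx(1.0)

    def test_tiny_group_falls_back_with_warning(self):
        res = compare_groups([1.0, 2.0], [3.0, 4.0, 5.0, 6.0])
        assert res.test == "mann-whitney"
        assert res.warning is not None

    def test_equal_proportions_chi_square_zero(self):
        a = np.array([1] * 10 + [0] * 10)
        res = compare_groups(a, a.copy(), kind="categorical")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(3, 60)] * 4))
    def test_chi_square_matches_closed_form(self, counts):
        """Pearson statistic equals n(ad-bc)^2 / product of margins."""
        a, b, c, d = counts
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        n = a + b + c + d
        expected = (n * (a * d - b * c) ** 2
                    / ((a + b) * (c + d) * (a + c) * (b + d)))
        assert stat == pytest.approx(expected, rel=1e-12)


class TestPearsonR2:
    def test_exact_line(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r2(x, 2 * x + 1)["r2"] == pytest.approx(1.0)

    def test_symmetric_orthogonality(self):
        x = np.array([-2.0, -1, 0, 1, 2])
        assert pearson_r2(x, x ** 2)["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 2.9, 4.2])
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        r2 = sxy ** 2 / (np.sum((x - x.mean()) ** 2)
                         * np.sum((y - y.mean()) ** 2))
        assert pearson_r2(x, y)["r2"] == pytest.approx(r2, rel=1e-12)

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDescribe:
    def test_median_iqr_by_linear_interpolation(self):
        out = describe([1, 2, 3, 4, 5])
        if out["style"] == "median_iqr":
            assert out["median"] == 3
            assert out["iqr_width"] == pytest.approx(2.0)
        else:  # a small uniform sample may pass the normality gate
            assert out["mean"] == pytest.approx(3.0)

    def test_skewed_vector_reports_median_iqr(self):
        rng = np.random.default_rng(0)
        out = describe(rng.lognormal(1, 1.2, 200))
        assert out["style"] == "median_iqr"

    def test_constant_vector_sd_zero(self):
        out = describe([4.0, 4.0, 4.0, 4.0])
        assert out["style"] == "mean_sd"
        assert out["sd"] == 0.0

    def test_single_value(self):
        out = describe([7.0])
        assert out["median"] == 7.0
        assert out["iqr_width"] is None
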