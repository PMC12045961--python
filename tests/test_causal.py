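"""Logistic engine, IPW, balance, doubly robust estimation, LR tests."""

import numpy as np
import pandas as pd
import pytest

from ctgartifact.causal import (
    balance_table,
    build_design,
    doubly_robust_effect,
    estimate_propensity,
    fit_logistic,
    ipw_weights,
    likelihood_ratio_test,
    quantile_dose_response,
    sandwich_cov,
)
from ctgartifact.cohort_stats import TwoByTwo, odds_ratio_2x2
from ctgartifact.errors import (
    ConfigurationError,
    PositivityError,
    RankDeficiencyError,
    SeparationError,
)


def expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def simulate_confounded(rng, n=20000, true_log_or=np.log(1.5), rare=True):
    """Binary exposure and outcome sharing two confounders."""
    x1 = rng.normal(size=n)
    x2 = (rng.random(n) < 0.5).astype(float)
    a = (rng.random(n) < expit(-1.2 + 0.7 * x1 + 0.5 * x2)).astype(float)
    b0 = -3.6 if rare else -0.5
    y = (rng.random(n) < expit(b0 + true_log_or * a + 0.6 * x1 + 0.4 * x2)).astype(
        float
    )
    return pd.DataFrame(
        dict(x1=x1, x2=x2, exposure_high=a.astype(bool), asphyxia=y.astype(bool))
    )


class TestFitLogistic:
    def test_intercept_only_recovers_logit_of_mean(self):
        y = np.repeat([1.0, 0.0], [25, 75])
        fit = fit_logistic(np.ones((100, 1)), y)
        assert fit.converged
        assert fit.params[0] == pytest.approx(np.log(1 / 3), abs=1e-8)

    def test_perfect_separation_raises(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.4).astype(float)
        with pytest.raises(RankDeficiencyError, match="dup"):
            fit_logistic(X, y, feature_names=["intercept", "x", "dup"])

    def test_recovers_known_coefficients_in_simulation(self, rng):
        n = 50000
        beta_true = np.array([-3.6, 0.4, -0.25])
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)
        fit = fit_logistic(X, y)
        se = fit.se()
        assert np.all(np.abs(fit.params - beta_true) < 3 * se)

    def test_matches_statsmodels_glm_oracle(self, rng):
        # independent cross-check of coefficients, covariance and llf,
        # including case weights
        import statsmodels.api as sm

        n = 3000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.random(n) < 0.4])
        y = (rng.random(n) < expit(-1 + X[:, 1] * 0.5 + 0.3 * X[:, 2])).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        fit = fit_logistic(X, y, weights=w)
        sm_fit = sm.GLM(
            y, X, family=sm.families.Binomial(), freq_weights=w
        ).fit()
        assert fit.params == pytest.approx(sm_fit.params, abs=1e-6)
        assert fit.llf == pytest.approx(sm_fit.llf, rel=1e-6)
        assert np.diag(fit.cov) == pytest.approx(
            np.diag(sm_fit.cov_params()), rel=1e-4
        )


class TestPropensityAndWeights:
    def test_null_model_scores_equal_marginal_rate(self, rng):
        n = 2000
        df = pd.DataFrame(
            dict(
                x=rng.normal(size=n),
                exposure_high=rng.random(n) < 0.2,
            )
        )
        fit = estimate_propensity(df, ["x"])
        rate = df.exposure_high.mean()
        assert np.allclose(fit.fitted, rate, atol=0.05)

    def test_saturated_single_binary_confounder(self, rng):
        n = 4000
        z = rng.random(n) < 0.5
        a = rng.random(n) < np.where(z, 0.4, 0.1)
        df = pd.DataFrame(dict(z=z.astype(float), exposure_high=a))
        fit = estimate_propensity(df, ["z"])
        for zval in (0.0, 1.0):
            stratum = df[df.z == zval]
            assert np.allclose(
                fit.fitted[(df.z == zval).to_numpy()],
                stratum.exposure_high.mean(),
                atol=1e-6,
            )

    def test_propensity_auc_matches_generator_discrimination(self, rng):
        # exposure from a known logistic model: the fitted scores should
        # discriminate as well as the true scores do
        n = 20000
        x = rng.normal(size=n)
        p = expit(-1.5 + 0.8 * x)
        a = rng.random(n) < p
        df = pd.DataFrame(dict(x=x, exposure_high=a))
        fit = estimate_propensity(df, ["x"])

        def auc(scores):
            r = pd.Series(scores).rank().to_numpy()
            n1 = a.sum()
            return (r[a].sum() - n1 * (n1 + 1) / 2) / (n1 * (~a).sum())

        assert auc(fit.fitted) == pytest.approx(auc(p), abs=0.01)

    def test_unstabilized_weights_closed_form(self):
        scores = np.array([0.5, 0.25, 0.8])
        exposure = np.array([True, True, False])
        w = ipw_weights(scores, exposure, stabilized=False, truncate_pct=None)
        assert w.weights == pytest.approx([2.0, 4.0, 5.0])

    def test_stabilized_weights_mean_near_one(self, rng):
        n = 10000
        x = rng.normal(size=n)
        p = expit(-1.5 + 0.8 * x)
        a = rng.random(n) < p
        w = ipw_weights(p, a, stabilized=True, truncate_pct=None)
        assert w.weights.mean() == pytest.approx(1.0, abs=0.02)

    def test_positivity_violation_raises(self):
        with pytest.raises(PositivityError):
            ipw_weights(np.array([0.0, 0.5]), np.array([True, False]))


class TestBalance:
    def test_identical_distributions_have_zero_smd(self, rng):
        n = 4000
        df = pd.DataFrame(
            dict(
                x=rng.normal(size=n),
                exposure_high=rng.random(n) < 0.3,
            )
        )
        bal = balance_table(df, ["x"], np.ones(n))
        assert abs(bal.smd_unweighted[0]) < 0.05

    def test_true_propensity_weighting_balances_confounder(self, rng):
        n = 10000
        x = rng.normal(size=n)
        p = expit(-1.2 + 0.8 * x)
        a = rng.random(n) < p
        df = pd.DataFrame(dict(x=x, exposure_high=a))
        w = ipw_weights(p, a)
        bal = balance_table(df, ["x"], w)
        assert abs(bal.smd_unweighted[0]) > 0.3  # confounded before weighting
        assert abs(bal.smd_weighted[0]) < 0.1

    def test_constant_covariate_has_zero_smd(self, rng):
        df = pd.DataFrame(
            dict(c=np.ones(100), exposure_high=rng.random(100) < 0.5)
        )
        bal = balance_table(df, ["c"], np.ones(100))
        assert bal.smd_unweighted[0] == 0.0


class TestDoublyRobust:
    def test_reduces_to_crude_or_with_equal_weights_no_covariates(self, rng):
        df = simulate_confounded(rng, n=5000)
        t = TwoByTwo(
            int((df.exposure_high & df.asphyxia).sum()),
            int((df.exposure_high & ~df.asphyxia).sum()),
            int((~df.exposure_high & df.asphyxia).sum()),
            int((~df.exposure_high & ~df.asphyxia).sum()),
        )
        crude = odds_ratio_2x2(t)
        est = doubly_robust_effect(df, [], weights=None)
        assert est.or_value == pytest.approx(crude.or_value, rel=1e-6)

    def test_removes_confounding_bias(self, rng):
        true = np.log(1.5)
        logors = []
        for _ in range(20):
            df = simulate_confounded(rng, n=20000, true_log_or=true)
            ps = estimate_propensity(df, ["x1", "x2"])
            w = ipw_weights(ps.fitted, df.exposure_high.to_numpy(bool))
            est = doubly_robust_effect(df, ["x1", "x2"], w)
            logors.append(np.log(est.or_value))
        assert abs(np.mean(logors) - true) < 0.05

    def test_single_arm_cohort_rejected(self, rng):
        df = simulate_confounded(rng, n=500)
        df["exposure_high"] = True
        with pytest.raises(ConfigurationError):
            doubly_robust_effect(df, ["x1"], weights=None)

    def test_bootstrap_ci_close_to_sandwich(self, rng):
        df = simulate_confounded(rng, n=8000, rare=False)
        est_sand = doubly_robust_effect(df, ["x1", "x2"], weights=None)
        est_boot = doubly_robust_effect(
            df, ["x1", "x2"], weights=None, bootstrap=200, seed=5
        )
        assert est_boot.ci_lo == pytest.approx(est_sand.ci_lo, rel=0.15)
        assert est_boot.ci_hi == pytest.approx(est_sand.ci_hi, rel=0.15)

    def test_sandwich_diagonal_nonnegative_and_rootn_shrink(self, rng):
        widths = []
        for n in (2000, 8000, 32000):
            df = simulate_confounded(rng, n=n, rare=False)
            a = df.exposure_high.to_numpy(float)
            X = np.column_stack([np.ones(n), a, df.x1])
            y = df.asphyxia.to_numpy(float)
            fit = fit_logistic(X, y)
            rcov = sandwich_cov(fit, X, y)
            assert np.all(np.diag(rcov) >= 0)
            widths.append(np.sqrt(rcov[1, 1]))
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.25)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.25)


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self, rng):
        df = simulate_confounded(rng, n=2000)
        X, names = build_design(df, ["x1"])
        fit = fit_logistic(X, df.asphyxia.to_numpy(float), feature_names=names)
        res = likelihood_ratio_test(fit, fit_logistic(
            X, df.asphyxia.to_numpy(float), feature_names=names
        ))
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0)

    def test_df_equals_added_parameter_count(self, rng):
        df = simulate_confounded(rng, n=3000)
        y = df.asphyxia.to_numpy(float)
        Xr, nr = build_design(df, ["x1"])
        bins = np.random.default_rng(0).integers(0, 5, len(df))
        ind = np.column_stack([(bins == b).astype(float) for b in range(1, 5)])
        Xf = np.hstack([Xr, ind])
        nf = nr + [f"bin_{b}" for b in range(1, 5)]
        res = likelihood_ratio_test(
            fit_logistic(Xf, y, feature_names=nf),
            fit_logistic(Xr, y, feature_names=nr),
        )
        assert res.df == 4
        assert res.statistic >= 0

    def test_invariant_to_affine_reparameterization(self, rng):
        df = simulate_confounded(rng, n=4000)
        y = df.asphyxia.to_numpy(float)
        X1, _ = build_design(df, ["x1", "x2"])
        X2 = X1.copy()
        X2[:, 1] = 3.0 * X1[:, 1] - 7.0  # affine transform of a column
        Xr, _ = build_design(df, [])
        f1 = fit_logistic(X1, y, feature_names=["c", "a", "b"])
        f2 = fit_logistic(X2, y, feature_names=["c", "a", "b"])
        r = fit_logistic(Xr, y, feature_names=["c"])
        s1 = likelihood_ratio_test(f1, r).statistic
        s2 = likelihood_ratio_test(f2, r).statistic
        assert s1 == pytest.approx(s2, abs=1e-5)

    def test_non_nested_models_rejected(self, rng):
        df = simulate_confounded(rng, n=500)
        y = df.asphyxia.to_numpy(float)
        Xa, na = build_design(df, ["x1"])
        Xb, nb = build_design(df, ["x2"])
        fa = fit_logistic(Xa, y, feature_names=na)
        fb = fit_logistic(Xb, y, feature_names=nb)
        with pytest.raises(ValueError):
            likelihood_ratio_test(fa, fb)


class TestQuantileDoseResponse:
    def test_null_dropout_gives_unit_bin_ors(self, rng):
        n = 20000
        df = simulate_confounded(rng, n=n)
        df["dropout_bin"] = rng.integers(0, 5, n)  # bins independent of outcome
        ests, lr = quantile_dose_response(df, "dropout_bin", ["x1", "x2"])
        for e in ests:
            assert e.ci_lo < 1.0 < e.ci_hi
        assert lr.df == 4

    def test_k2_reduces_to_binary_exposure_model(self, rng):
        df = simulate_confounded(rng, n=10000)
        df["dropout_bin"] = df["exposure_high"].astype(int)
        ests, _ = quantile_dose_response(df, "dropout_bin", ["x1", "x2"])
        direct = doubly_robust_effect(df, ["x1", "x2"], weights=None)
        assert len(ests) == 1
        assert ests[0].or_value == pytest.approx(direct.or_value, rel=1e-6)

    def test_monotone_generator_yields_monotone_bin_estimates(self, rng):
        # log-odds linear in dropout -> bin point estimates rise with bin,
        # checked on replicate means to absorb sampling noise
        mean_logors = np.zeros(4)
        reps = 10
        for _ in range(reps):
            n = 20000
            d = rng.beta(1.5, 5, n)
            y = rng.random(n) < expit(-3.5 + 2.0 * d)
            df = pd.DataFrame(dict(asphyxia=y))
            df["dropout_bin"] = pd.qcut(np.log(d + 1e-4), 5, labels=False)
            ests, _ = quantile_dose_response(df, "dropout_bin", [])
            mean_logors += np.log([e.or_value for e in ests]) / reps
        assert np.all(np.diff(mean_logors) > -0.05)
        assert mean_logors[-1] > mean_logors[0]

    def test_empty_bin_is_an_error(self, rng):
        df = simulate_confounded(rng, n=1000)
        df["dropout_bin"] = 0
        df.loc[df.index[:100], "dropout_bin"] = 2  # bin 1 empty
        with pytest.raises(ConfigurationError):
            quantile_dose_response(df, "dropout_bin", ["x1"])
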