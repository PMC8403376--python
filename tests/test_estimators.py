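import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.linalg import toeplitz
from scipy.stats import multivariate_normal

from itseval.core import ITSDesign, ModelParams, build_design_matrix, true_mean
from itseval.estimators import (
    METHODS,
    SegmentedITS,
    arima_loglik,
    arima_profile_loglik,
    batch_ols,
    confidence_interval,
    fit_ols,
    pw_transform,
    reml_loglik,
    reml_profile_loglik,
    satterthwaite_df,
)
from itseval.simulate import TimeSeries

from conftest import one_series, series_matrix


def random_fixtures(n_fixtures=100, n=12, seed=5):
    design = ITSDesign.midpoint(n)
    params = ModelParams(beta2=1.0, beta3=0.1, rho=0.4)
    for i in range(n_fixtures):
        yield one_series(params, design, seed=1000 + i)


class TestOLSAndNeweyWest:
    def test_noiseless_exact_recovery(self):
        params = ModelParams(beta0=1.0, beta1=0.5, beta2=2.0, beta3=0.1, sigma2=0.0)
        design = ITSDesign.midpoint(10)
        ts = TimeSeries(true_mean(params, design), design)
        fit = fit_ols(ts)
        assert np.allclose(fit.params, params.beta, atol=1e-10)
        assert np.all(fit.bse < 1e-8)

    def test_ols_matches_library_on_random_fixtures(self):
        # independent implementation check against statsmodels OLS
        for ts in random_fixtures():
            X = build_design_matrix(ts.design)
            ref = sm.OLS(ts.y, np.asarray(X)).fit()
            fit = fit_ols(ts)
            assert np.allclose(fit.params, ref.params, rtol=1e-6)
            assert np.allclose(fit.bse, ref.bse, rtol=1e-6)
            assert np.isclose(fit.sigma2, ref.scale, rtol=1e-6)

    def test_newey_west_matches_library_hac(self):
        for ts in random_fixtures(n_fixtures=50):
            X = np.asarray(build_design_matrix(ts.design))
            ref = sm.OLS(ts.y, X).fit(
                cov_type="HAC", cov_kwds={"maxlags": 1, "use_correction": True}
            )
            fit = SegmentedITS.from_series(ts).fit_newey_west(lag=1)
            assert np.allclose(fit.bse, ref.bse, rtol=1e-6)

    def test_newey_west_brute_force_sandwich(self, ar_series_10):
        # literal double-sum Bartlett sandwich on a 10-point fixture
        ts = ar_series_10
        X = np.asarray(build_design_matrix(ts.design))
        n, lag = 10, 1
        fit = SegmentedITS.from_series(ts).fit_newey_west(lag=lag)
        e = ts.y - X @ fit.params
        S = np.zeros((4, 4))
        for t in range(n):
            for s in range(n):
                ell = abs(t - s)
                w = 1.0 - ell / (lag + 1.0) if ell <= lag else 0.0
                S += w * e[t] * e[s] * np.outer(X[t], X[s])
        XtX_inv = np.linalg.inv(X.T @ X)
        cov = n / (n - 4.0) * XtX_inv @ S @ XtX_inv
        assert np.allclose(fit.bse, np.sqrt(np.diag(cov)), rtol=1e-10)

    def test_lag_zero_reduces_to_hc1_sandwich(self, ar_series_10):
        X = np.asarray(build_design_matrix(ar_series_10.design))
        ref = sm.OLS(ar_series_10.y, X).fit(cov_type="HC1")
        fit = SegmentedITS.from_series(ar_series_10).fit_newey_west(lag=0)
        assert np.allclose(fit.bse, ref.bse, rtol=1e-8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_hac_adjustment_never_moves_coefficients(self, seed):
        ts = one_series(
            ModelParams(beta2=2.0, rho=0.6), ITSDesign.midpoint(16), seed=seed
        )
        m = SegmentedITS.from_series(ts)
        assert np.array_equal(m.fit_ols().params, m.fit_newey_west().params)

    def test_batch_ols_matches_single_fits(self):
        design = ITSDesign.midpoint(14)
        Y = series_matrix(ModelParams(beta2=1.0, rho=0.3), design, 5, seed=2)
        B, S, R = batch_ols(Y, design)
        for r in range(5):
            fit = SegmentedITS(Y[r], design=design).fit_ols()
            assert np.allclose(B[r], fit.params, rtol=1e-12)
            assert np.allclose(S[r], fit.bse, rtol=1e-12)
            assert np.allclose(R[r], fit.resid, atol=1e-12)


class TestPraisWinsten:
    def test_single_iteration_matches_hand_rolled_transform(self, ar_series_10):
        ts = ar_series_10
        X = np.asarray(build_design_matrix(ts.design))
        # hand-rolled: OLS -> rho from residual autocovariance -> PW
        # transform -> OLS on transformed data
        b_ols = np.linalg.lstsq(X, ts.y, rcond=None)[0]
        e = ts.y - X @ b_ols
        rho = (e[1:] @ e[:-1]) / (e @ e)
        Ty, TX = pw_transform(ts.y, rho), pw_transform(X, rho)
        b_hand = np.linalg.lstsq(TX, Ty, rcond=None)[0]
        fit = SegmentedITS.from_series(ts).fit_prais_winsten(max_iter=1)
        assert np.isclose(fit.rho, rho, rtol=1e-12)
        assert np.allclose(fit.params, b_hand, rtol=1e-10)

    def test_gls_step_matches_library_at_converged_rho(self):
        # at the converged rho-hat, PW is exact GLS under the AR(1)
        # covariance; statsmodels GLS with that covariance must agree
        for ts in random_fixtures(n_fixtures=100):
            fit = SegmentedITS.from_series(ts).fit_prais_winsten()
            if not fit.converged:
                continue
            V = toeplitz(fit.rho ** np.arange(ts.design.n_points))
            ref = sm.GLS(ts.y, np.asarray(build_design_matrix(ts.design)), sigma=V).fit()
            assert np.allclose(fit.params, ref.params, rtol=1e-6)
            assert np.allclose(fit.bse, ref.bse, rtol=1e-6)

    def test_zero_rho_is_identity_transform(self):
        params = ModelParams(beta2=2.0, beta3=0.1, sigma2=0.0)
        design = ITSDesign.midpoint(8)
        ts = TimeSeries(true_mean(params, design), design)
        m = SegmentedITS.from_series(ts)
        pw, ols = m.fit_prais_winsten(), m.fit_ols()
        assert pw.rho == 0.0
        assert pw.converged
        assert np.array_equal(pw.params, ols.params)

    def test_max_iter_exhaustion_flags_nonconvergence(self, ar_series_48):
        fit = SegmentedITS.from_series(ar_series_48).fit_prais_winsten(
            tol=1e-14, max_iter=2
        )
        assert not fit.converged

    def test_cochrane_orcutt_drops_first_observation(self, ar_series_10):
        co = SegmentedITS.from_series(ar_series_10).fit_cochrane_orcutt(max_iter=1)
        ts = ar_series_10
        X = np.asarray(build_design_matrix(ts.design))
        b_ols = np.linalg.lstsq(X, ts.y, rcond=None)[0]
        e = ts.y - X @ b_ols
        rho = (e[1:] @ e[:-1]) / (e @ e)
        Ty = ts.y[1:] - rho * ts.y[:-1]
        TX = X[1:] - rho * X[:-1]
        b_hand = np.linalg.lstsq(TX, Ty, rcond=None)[0]
        assert np.allclose(co.params, b_hand, rtol=1e-10)


class TestREML:
    def test_restricted_loglik_matches_dense_matrix_oracle(self, ar_series_10):
        # literal dense implementation with explicit inverses/determinants
        ts = ar_series_10
        X = np.asarray(build_design_matrix(ts.design))
        y, (n, k) = ts.y, X.shape
        for rho in (-0.7, -0.2, 0.0, 0.3, 0.6, 0.9):
            V = toeplitz(rho ** np.arange(n))
            Vinv = np.linalg.inv(V)
            XtVX = X.T @ Vinv @ X
            beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
            r = y - X @ beta
            q = r @ Vinv @ r
            sigma2 = q / (n - k)
            dense = -0.5 * (
                (n - k) * np.log(2 * np.pi * sigma2)
                + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtVX)[1]
                + (n - k)
            )
            assert abs(dense - reml_profile_loglik(y, X, rho)) < 1e-8
            assert abs(
                reml_loglik(y, X, rho, 1.3)
                - (-0.5)
                * (
                    (n - k) * np.log(2 * np.pi * 1.3)
                    + np.linalg.slogdet(V)[1]
                    + np.linalg.slogdet(XtVX)[1]
                    + q / 1.3
                )
            ) < 1e-8

    def test_fixed_zero_rho_reproduces_ols(self, ar_series_48):
        m = SegmentedITS.from_series(ar_series_48)
        reml = m.fit_reml(fix_rho=0.0)
        ols = m.fit_ols()
        assert np.allclose(reml.params, ols.params, rtol=1e-12)
        assert np.isclose(reml.sigma2, ols.sigma2, rtol=1e-12)
        assert np.allclose(reml.bse, ols.bse, rtol=1e-12)

    def test_optimizer_finds_profile_maximum(self, ar_series_48):
        ts = ar_series_48
        X = np.asarray(build_design_matrix(ts.design))
        fit = SegmentedITS.from_series(ts).fit_reml()
        assert fit.converged
        ll_hat = reml_profile_loglik(ts.y, X, fit.rho)
        grid = np.linspace(-0.99, 0.99, 397)
        assert ll_hat >= max(reml_profile_loglik(ts.y, X, r) for r in grid) - 1e-6

    def test_short_series_boundary_nonconvergence_occurs(self):
        # optimum pinned to the rho boundary is flagged, mirroring the
        # frequent REML failures on very short series
        design = ITSDesign.midpoint(10)
        Y = series_matrix(
            ModelParams(beta2=2.0, beta3=0.1, rho=0.4), design, 200, seed=3
        )
        conv = [
            SegmentedITS(Y[r], design=design).fit_reml().converged
            for r in range(200)
        ]
        frac = np.mean(conv)
        assert 0.4 < frac < 0.95

    def test_satterthwaite_reduces_to_residual_df_with_known_rho(self, ar_series_48):
        ts = ar_series_48
        X = np.asarray(build_design_matrix(ts.design))
        fit = SegmentedITS.from_series(ts).fit_reml()
        nu, flag = satterthwaite_df(
            ts.y, X, fit.rho, fit.sigma2 / (1 - fit.rho**2), 2, vary_rho=False
        )
        assert not flag
        assert np.isclose(nu, 44.0, rtol=1e-4)

    def test_satterthwaite_stable_under_step_halving(self, ar_series_48):
        ts = ar_series_48
        X = np.asarray(build_design_matrix(ts.design))
        fit = SegmentedITS.from_series(ts).fit_reml()
        s2 = fit.sigma2 / (1 - fit.rho**2)
        nu1, _ = satterthwaite_df(ts.y, X, fit.rho, s2, 2, step=1e-4)
        nu2, _ = satterthwaite_df(ts.y, X, fit.rho, s2, 2, step=5e-5)
        assert np.isclose(nu1, nu2, rtol=1e-3)

    def test_satterthwaite_df_floored_at_two(self):
        design = ITSDesign.midpoint(8)
        y = series_matrix(
            ModelParams(beta2=2.0, beta3=0.1, rho=0.8), design, 1, seed=0
        )[0]
        fit = SegmentedITS(y, design=design).fit_reml(satterthwaite=True)
        assert fit.converged
        assert np.all(fit.df >= 2.0)
        assert fit.df_flags.any()  # at least one raw df was below 2

    def test_satterthwaite_estimates_equal_reml_estimates(self, ar_series_48):
        m = SegmentedITS.from_series(ar_series_48)
        assert np.array_equal(
            m.fit_reml().params, m.fit_reml(satterthwaite=True).params
        )


class TestARIMA:
    def test_loglik_matches_multivariate_normal_density(self, ar_series_10):
        ts = ar_series_10
        X = np.asarray(build_design_matrix(ts.design))
        beta = np.array([0.2, 0.1, 1.5, 0.05])
        for rho, s2 in [(-0.5, 0.8), (0.0, 1.0), (0.4, 2.0), (0.9, 0.3)]:
            V = toeplitz(rho ** np.arange(10))
            dense = multivariate_normal.logpdf(ts.y, X @ beta, s2 * V)
            assert abs(dense - arima_loglik(ts.y, X, beta, rho, s2)) < 1e-8

    def test_profile_consistent_with_joint_loglik(self, ar_series_10):
        ts = ar_series_10
        X = np.asarray(build_design_matrix(ts.design))
        from itseval.estimators import _gls_at_rho

        for rho in (-0.3, 0.2, 0.7):
            beta, rss_T, _ = _gls_at_rho(ts.y, X, rho)
            s2 = rss_T / (1 - rho**2) / 10
            assert np.isclose(
                arima_profile_loglik(ts.y, X, rho),
                arima_loglik(ts.y, X, beta, rho, s2),
                rtol=1e-12,
            )

    def test_near_noiseless_long_series_recovers_truth(self):
        params = ModelParams(
            beta0=1.0, beta1=0.05, beta2=2.0, beta3=0.1, rho=0.5, sigma2=0.01
        )
        design = ITSDesign.midpoint(1000)
        y = series_matrix(params, design, 1, seed=7)[0]
        fit = SegmentedITS(y, design=design).fit_arima()
        assert fit.converged
        assert np.allclose(fit.params, params.beta, atol=0.05)
        assert abs(fit.rho - 0.5) < 0.1

    def test_joint_information_se_exceeds_gls_se(self, ar_series_48):
        # propagating rho uncertainty cannot shrink the coefficient SEs
        m = SegmentedITS.from_series(ar_series_48)
        full = m.fit_arima(compute_se=True)
        gls = m.fit_arima(compute_se=False)
        assert full.converged
        assert np.array_equal(full.params, gls.params)
        assert np.all(full.bse[2:] > 0)

    def test_normal_reference_option(self, ar_series_48):
        fit = SegmentedITS.from_series(ar_series_48).fit_arima(df="normal")
        assert np.all(np.isinf(fit.df))


class TestResultContract:
    def test_registry_dispatch(self, ar_series_10):
        m = SegmentedITS.from_series(ar_series_10)
        assert set(METHODS) == {"OLS", "NW", "PW", "REML", "REML-Satt", "ARIMA"}
        assert np.array_equal(m.fit("PW").params, m.fit_prais_winsten().params)
        with pytest.raises(ValueError):
            m.fit("GLSAR")

    def test_confidence_interval_t_quantile(self):
        fit = _fake_fit(estimate=2.0, se=0.5, df=20.0)
        ci = confidence_interval(fit, 2)
        assert np.isclose(ci.ci_low, 2.0 - 2.086 * 0.5, atol=1e-3)
        assert np.isclose(ci.ci_high, 2.0 + 2.086 * 0.5, atol=1e-3)
        assert ci.ci_low <= ci.estimate <= ci.ci_high

    def test_confidence_interval_normal_limit(self):
        fit = _fake_fit(estimate=1.0, se=1.0, df=np.inf)
        ci = confidence_interval(fit, 2)
        assert np.isclose(ci.ci_high - 1.0, 1.959964, atol=1e-5)

    def test_degenerate_interval_at_zero_se(self):
        fit = _fake_fit(estimate=2.0, se=0.0, df=10.0)
        ci = confidence_interval(fit, 2)
        assert ci.ci_low == ci.ci_high == 2.0
        assert ci.p_value == 0.0

    def test_nonconverged_fit_rejected(self, ar_series_10):
        fit = SegmentedITS.from_series(ar_series_10).fit_ols()
        fit.converged = False
        with pytest.raises(ValueError):
            confidence_interval(fit, 2)

    def test_summary_renders(self, ar_series_48):
        text = SegmentedITS.from_series(ar_series_48).fit_reml().summary()
        assert "level_change" in text and "REML" in text


def _fake_fit(estimate, se, df):
    ts = one_series(ModelParams(beta2=1.0), ITSDesign.midpoint(10), seed=1)
    fit = SegmentedITS.from_series(ts).fit_ols()
    fit.params = np.array([0.0, 0.0, estimate, 0.0])
    fit.bse = np.array([1.0, 1.0, se, 1.0])
    fit.df = np.full(4, df)
    return fit
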