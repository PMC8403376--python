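"""Estimation methods for segmented ITS regression with AR(1) errors.

The model surface follows the statsmodels convention: :class:`SegmentedITS`
is built from the outcome vector and design, and each ``fit_*`` method
returns an :class:`ITSResults` carrying the coefficient estimates, their
model-based standard errors, the inference degrees of freedom, the
autocorrelation and innovation-variance estimates, and a convergence flag.

Six procedures share this contract:

``OLS``
    Ordinary least squares; SEs ignore autocorrelation.
``NW``
    OLS coefficients with Newey-West (Bartlett-kernel, lag 1 by default)
    heteroskedasticity- and autocorrelation-consistent SEs, with the
    small-sample factor ``N / (N - 4)``.
``PW``
    Iterated Prais-Winsten feasible GLS: the lag-1 residual
    autocorrelation is estimated, the data are quasi-differenced (keeping
    a scaled first observation), and the two steps alternate until the
    autocorrelation estimate stabilises.
``REML`` / ``REML-Satt``
    Restricted maximum likelihood for the AR(1) error covariance, with
    optional Satterthwaite approximation of the per-coefficient t
    reference degrees of freedom (floored at 2).
``ARIMA``
    Exact Gaussian maximum likelihood for the regression with stationary
    AR(1) errors (an ARMAX / ARIMA(1,0,0)-with-regressors fit); SEs come
    from the inverse observed information of the *joint* likelihood, so
    uncertainty in the autocorrelation estimate propagates into the
    coefficient SEs.

``sigma2`` in the results is always the innovation (white-noise) variance
for the AR-aware methods, and the residual variance for OLS/NW (these
coincide when rho = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.linalg import inv, slogdet, solve
from scipy import optimize, stats

from .core import ITSDesign, build_design_matrix
from .simulate import TimeSeries

__all__ = [
    "SegmentedITS",
    "ITSResults",
    "IntervalEstimate",
    "METHODS",
    "fit_ols",
    "fit_newey_west",
    "fit_prais_winsten",
    "fit_cochrane_orcutt",
    "fit_reml_ar1",
    "fit_arima_ml",
    "confidence_interval",
    "satterthwaite_df",
    "pw_transform",
    "reml_loglik",
    "reml_profile_loglik",
    "arima_loglik",
    "arima_profile_loglik",
    "batch_ols",
]

_RHO_BOUND = 0.999
_BOUNDARY_TOL = 1e-3


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a two-sided t confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float = 0.95


class ITSResults:
    """Common result contract for all segmented-ITS fitting methods.

    Attributes
    ----------
    method : str
        Registry label ("OLS", "NW", "PW", "REML", "REML-Satt", "ARIMA").
    params : ndarray (4,)
        Coefficient estimates (intercept, pre slope, level change, slope
        change).
    bse : ndarray (4,)
        Model-based standard errors.
    df : ndarray (4,)
        Per-coefficient inference degrees of freedom for the t reference
        distribution (``inf`` selects the normal reference).
    rho : float
        Estimated lag-1 autocorrelation (``nan`` for OLS/NW).
    sigma2 : float
        Innovation-variance estimate (residual variance for OLS/NW).
    converged : bool
        False when the estimation procedure failed; estimates are then
        flagged unusable and excluded from performance summaries.
    n_iter : int
        Iteration count where applicable.
    resid : ndarray (N,)
        Raw-scale residuals ``y - X @ params``.
    """

    def __init__(
        self,
        method: str,
        model: "SegmentedITS",
        params: np.ndarray,
        bse: np.ndarray,
        df,
        rho: float,
        sigma2: float,
        converged: bool = True,
        n_iter: int = 0,
        df_flags=None,
    ):
        self.method = method
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.bse = np.asarray(bse, dtype=float)
        self.df = np.broadcast_to(np.asarray(df, dtype=float), (4,)).copy()
        self.rho = float(rho)
        self.sigma2 = float(sigma2)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.df_flags = (
            np.zeros(4, dtype=bool) if df_flags is None else np.asarray(df_flags)
        )
        self.resid = model.y - model.X @ self.params

    # aliases matching the functional naming used elsewhere
    @property
    def coef(self) -> np.ndarray:
        return self.params

    @property
    def se(self) -> np.ndarray:
        return self.bse

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        out = np.empty(4)
        for i in range(4):
            out[i] = confidence_interval(self, i, _check=False).p_value
        return out

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(4, 2) array of two-sided t confidence limits."""
        out = np.empty((4, 2))
        for i in range(4):
            ci = confidence_interval(self, i, level=level, _check=False)
            out[i] = (ci.ci_low, ci.ci_high)
        return out

    def summary(self, level: float = 0.95) -> str:
        names = ["intercept", "pre_slope", "level_change", "slope_change"]
        lines = [
            f"Segmented ITS regression — method: {self.method}",
            f"N = {self.model.design.n_points}, interruption at t = "
            f"{self.model.design.interruption_index}",
            f"rho_hat = {self.rho:.4f}  sigma2_hat = {self.sigma2:.4f}  "
            f"converged = {self.converged}",
            "-" * 72,
            f"{'':>14}{'coef':>10}{'se':>10}{'df':>8}{'t':>8}{'P>|t|':>9}"
            f"{'[CI low':>10}{'CI high]':>10}",
        ]
        ci = self.conf_int(level)
        t = self.tvalues
        p = self.pvalues
        for i, nm in enumerate(names):
            lines.append(
                f"{nm:>14}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.df[i]:>8.1f}{t[i]:>8.2f}{p[i]:>9.4f}"
                f"{ci[i, 0]:>10.4f}{ci[i, 1]:>10.4f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ITSResults {self.method} params={np.round(self.params, 4)} "
            f"converged={self.converged}>"
        )


def confidence_interval(
    fit: ITSResults, index: int, level: float = 0.95, _check: bool = True
) -> IntervalEstimate:
    """Two-sided t confidence interval and p-value for one coefficient.

    Uses the per-coefficient degrees of freedom stored on the fit;
    ``df = inf`` reproduces the normal-reference interval.  Rejects
    non-converged fits (their SEs are unusable).
    """
    if _check and not fit.converged:
        raise ValueError("confidence interval requested from a non-converged fit")
    est = float(fit.params[index])
    se = float(fit.bse[index])
    df = float(fit.df[index])
    if se == 0.0:
        return IntervalEstimate(est, est, est, 1.0 if est == 0.0 else 0.0, level)
    tcrit = (
        stats.norm.ppf(0.5 + level / 2)
        if np.isinf(df)
        else stats.t.ppf(0.5 + level / 2, df)
    )
    tval = est / se
    p = (
        2 * stats.norm.sf(abs(tval))
        if np.isinf(df)
        else 2 * stats.t.sf(abs(tval), df)
    )
    return IntervalEstimate(est, est - tcrit * se, est + tcrit * se, float(p), level)


# ---------------------------------------------------------------------------
# AR(1) GLS building blocks
# ---------------------------------------------------------------------------


def pw_transform(Z: np.ndarray, rho: float) -> np.ndarray:
    """Prais-Winsten quasi-differencing transform.

    Row 1 is scaled by ``sqrt(1 - rho^2)``; row t >= 2 becomes
    ``row_t - rho * row_{t-1}``.  Applied to both X and y this whitens an
    AR(1) error covariance exactly: with ``V_ij = rho^|i-j|`` we have
    ``T V T' = (1 - rho^2) I``.
    """
    Z = np.asarray(Z, dtype=float)
    out = np.empty_like(Z)
    out[0] = np.sqrt(1.0 - rho * rho) * Z[0]
    out[1:] = Z[1:] - rho * Z[:-1]
    return out


def _gls_at_rho(y: np.ndarray, X: np.ndarray, rho: float):
    """GLS under V(rho): returns (beta, rss_T, XtX_T) on the transformed scale."""
    Ty = pw_transform(y, rho)
    TX = pw_transform(X, rho)
    XtX = TX.T @ TX
    beta = solve(XtX, TX.T @ Ty)
    r = Ty - TX @ beta
    return beta, float(r @ r), XtX


def reml_loglik(y: np.ndarray, X: np.ndarray, rho: float, sigma2: float) -> float:
    """Restricted log-likelihood at (rho, sigma2).

    ``sigma2`` is the *marginal* error variance in the parameterisation
    ``y ~ N(X beta, sigma2 * V(rho))`` with ``V_ij = rho^|i-j|``; beta is
    profiled out at its GLS value.
    """
    n, k = X.shape
    if sigma2 <= 0.0:
        return -np.inf
    _, rss_T, XtX = _gls_at_rho(y, X, rho)
    one_m = 1.0 - rho * rho
    q = rss_T / one_m
    logdet_V = (n - 1) * np.log(one_m)
    logdet_XVX = slogdet(XtX)[1] - k * np.log(one_m)
    return -0.5 * (
        (n - k) * np.log(2 * np.pi * sigma2) + logdet_V + logdet_XVX + q / sigma2
    )


def reml_profile_loglik(y: np.ndarray, X: np.ndarray, rho: float) -> float:
    """Restricted log-likelihood profiled over sigma2 (and beta)."""
    n, k = X.shape
    _, rss_T, XtX = _gls_at_rho(y, X, rho)
    one_m = 1.0 - rho * rho
    q = rss_T / one_m
    sigma2 = max(q / (n - k), 1e-300)
    logdet_V = (n - 1) * np.log(one_m)
    logdet_XVX = slogdet(XtX)[1] - k * np.log(one_m)
    return -0.5 * (
        (n - k) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_V + logdet_XVX
    )


def arima_loglik(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, rho: float, sigma2: float
) -> float:
    """Exact Gaussian log-likelihood of the AR(1)-error regression.

    ``sigma2`` is the marginal error variance (``y ~ N(X beta,
    sigma2 * V(rho))``); the innovation variance is ``sigma2*(1-rho^2)``.
    """
    n = len(y)
    r = y - X @ beta
    Tr = pw_transform(r, rho)
    one_m = 1.0 - rho * rho
    q = float(Tr @ Tr) / one_m
    logdet_V = (n - 1) * np.log(one_m)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_V + q / sigma2)


def arima_profile_loglik(y: np.ndarray, X: np.ndarray, rho: float) -> float:
    """Joint ML log-likelihood profiled over beta (GLS) and sigma2 (divisor N)."""
    n, _ = X.shape
    _, rss_T, _ = _gls_at_rho(y, X, rho)
    one_m = 1.0 - rho * rho
    sigma2 = max(rss_T / one_m / n, 1e-300)
    logdet_V = (n - 1) * np.log(one_m)
    return -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_V)


def _fd_hessian(f, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with per-parameter relative steps."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def satterthwaite_df(
    y: np.ndarray,
    X: np.ndarray,
    rho: float,
    sigma2: float,
    index: int,
    vary_rho: bool = True,
    step: float = 1e-4,
) -> tuple[float, bool]:
    """Satterthwaite degrees of freedom for one coefficient of a REML fit.

    The contrast variance is ``psi = sigma2 * [(X'V^-1 X)^-1]_ii``; the
    approximation is ``nu = 2 psi^2 / (g' I^-1 g)`` with ``g`` the
    gradient of psi with respect to the variance parameters (numerical
    differentiation) and ``I`` the observed information of the restricted
    likelihood.  ``vary_rho=False`` treats rho as known, in which case nu
    reduces to the classical ``N - k`` for the chi-square variance of the
    REML sigma2 estimate.

    Returns ``(max(nu, 2), flag)``; the flag marks a singular information
    matrix or a nonsensical nu, for which the floor value 2 is returned.
    """
    n, k = X.shape

    def a_of_rho(r: float) -> float:
        _, _, XtX = _gls_at_rho(y, X, r)
        XtVinvX = XtX / (1.0 - r * r)
        return inv(XtVinvX)[index, index]

    a0 = a_of_rho(rho)
    psi = sigma2 * a0
    # degenerate fits (e.g. sigma2 ~ 0) overflow the likelihood in the
    # finite differences; the NaN checks below catch them
    with np.errstate(all="ignore"):
        if vary_rho:
            h = min(step, (_RHO_BOUND - abs(rho)) / 2 + 1e-12)
            da = (a_of_rho(rho + h) - a_of_rho(rho - h)) / (2.0 * h)
            g = np.array([sigma2 * da, a0])
            f = lambda th: reml_loglik(y, X, th[0], th[1])
            H = _fd_hessian(f, np.array([rho, sigma2]), rel=step)
        else:
            g = np.array([a0])
            f = lambda th: reml_loglik(y, X, rho, th[0])
            H = _fd_hessian(f, np.array([sigma2]), rel=step)
    I = -H
    try:
        denom = float(g @ solve(I, g))
    except np.linalg.LinAlgError:
        return 2.0, True
    if not np.isfinite(denom) or denom <= 0:
        return 2.0, True
    nu = 2.0 * psi * psi / denom
    if not np.isfinite(nu):
        return 2.0, True
    return (max(nu, 2.0), nu < 2.0)


# ---------------------------------------------------------------------------
# the model class
# ---------------------------------------------------------------------------


class SegmentedITS:
    """Segmented linear regression model for a single-interruption ITS.

    Parameters
    ----------
    y : array-like, shape (N,)
        Outcome values at times ``t = 1, ..., N``.
    design : ITSDesign, optional
        Series length and interruption index.  Alternatively pass
        ``interruption_index`` and the design is built from ``len(y)``.

    Examples
    --------
    >>> model = SegmentedITS(y, interruption_index=25)
    >>> res = model.fit("REML")
    >>> print(res.summary())
    """

    def __init__(self, y, design: ITSDesign | None = None, interruption_index=None):
        y = np.asarray(y, dtype=float)
        if design is None:
            if interruption_index is None:
                raise ValueError("provide either design or interruption_index")
            design = ITSDesign(len(y), int(interruption_index))
        self.design = design
        self.X = np.asarray(build_design_matrix(design))
        if y.shape != (design.n_points,):
            raise ValueError("y length does not match design")
        self.y = y

    @classmethod
    def from_series(cls, series: TimeSeries) -> "SegmentedITS":
        return cls(series.y, design=series.design)

    @property
    def df_resid(self) -> int:
        return self.design.n_points - 4

    def fit(self, method: str = "OLS", **kwargs) -> ITSResults:
        """Fit by registry label ("OLS", "NW", "PW", "REML", "REML-Satt",
        "ARIMA")."""
        try:
            fitter = METHODS[method]
        except KeyError:
            raise ValueError(
                f"unknown method {method!r}; choose from {sorted(METHODS)}"
            ) from None
        return fitter(self, **kwargs)

    # -- OLS / Newey-West -------------------------------------------------

    def fit_ols(self) -> ITSResults:
        """Ordinary least squares; SEs valid only under independent errors."""
        X, y = self.X, self.y
        n = self.design.n_points
        XtX_inv = inv(X.T @ X)
        beta = XtX_inv @ (X.T @ y)
        e = y - X @ beta
        sigma2 = float(e @ e) / (n - 4)
        bse = np.sqrt(sigma2 * np.diag(XtX_inv))
        return ITSResults("OLS", self, beta, bse, n - 4, np.nan, sigma2)

    def fit_newey_west(self, lag: int = 1) -> ITSResults:
        """OLS coefficients with Bartlett-kernel HAC standard errors.

        Kernel weight ``w_l = 1 - l/(lag+1)`` and small-sample factor
        ``N/(N-4)``; ``lag=0`` gives the heteroskedasticity-only sandwich.
        """
        X, y = self.X, self.y
        n = self.design.n_points
        XtX_inv = inv(X.T @ X)
        beta = XtX_inv @ (X.T @ y)
        e = y - X @ beta
        sigma2 = float(e @ e) / (n - 4)
        Xe = X * e[:, None]
        S = Xe.T @ Xe
        for ell in range(1, lag + 1):
            w = 1.0 - ell / (lag + 1.0)
            G = Xe[ell:].T @ Xe[:-ell]
            S += w * (G + G.T)
        cov = (n / (n - 4.0)) * XtX_inv @ S @ XtX_inv
        bse = np.sqrt(np.diag(cov))
        return ITSResults("NW", self, beta, bse, n - 4, np.nan, sigma2)

    # -- feasible GLS -----------------------------------------------------

    def _iterated_gls(
        self,
        method: str,
        drop_first: bool,
        tol: float,
        max_iter: int,
        rho_estimator: str,
    ) -> ITSResults:
        X, y = self.X, self.y
        n = self.design.n_points
        df = (n - 5) if drop_first else (n - 4)

        def transform(Z, rho):
            T = pw_transform(Z, rho)
            return T[1:] if drop_first else T

        XtX_inv = inv(X.T @ X)
        beta = XtX_inv @ (X.T @ y)
        rho_old = 0.0
        history: list[float] = []
        rho = 0.0
        converged = False
        TX = X
        Ty = y
        it = 0
        for it in range(1, max_iter + 1):
            e = y - X @ beta
            denom = float(e @ e)
            # a numerically perfect fit: no autocorrelation to estimate
            if denom <= 1e-24 * max(1.0, float(y @ y)):
                rho = 0.0
                converged = True
                TX, Ty = X, y
                break
            if rho_estimator == "autocov":
                rho = float(e[1:] @ e[:-1]) / denom
            elif rho_estimator == "regression":
                d2 = float(e[:-1] @ e[:-1])
                rho = float(e[1:] @ e[:-1]) / d2 if d2 > 0 else 0.0
            else:
                raise ValueError(f"unknown rho_estimator {rho_estimator!r}")
            if abs(rho) >= 1.0:
                converged = False
                break
            Ty = transform(y, rho)
            TX = transform(X, rho)
            beta = solve(TX.T @ TX, TX.T @ Ty)
            if abs(rho - rho_old) < tol:
                converged = True
                break
            if any(abs(rho - h) < tol for h in history[-4:]):
                converged = False  # oscillation between iterates
                break
            history.append(rho_old)
            rho_old = rho
        if abs(rho) >= 1.0:
            # unusable: report the last stable state, flagged
            rho = np.clip(rho, -_RHO_BOUND, _RHO_BOUND)
            Ty = transform(y, rho)
            TX = transform(X, rho)
            beta = solve(TX.T @ TX, TX.T @ Ty)
        r_T = Ty - TX @ beta
        sigma2 = float(r_T @ r_T) / df
        cov = sigma2 * inv(TX.T @ TX)
        bse = np.sqrt(np.diag(cov))
        return ITSResults(
            method, self, beta, bse, df, rho, sigma2, converged=converged, n_iter=it
        )

    def fit_prais_winsten(
        self,
        tol: float = 1e-6,
        max_iter: int = 100,
        rho_estimator: str = "autocov",
    ) -> ITSResults:
        """Iterated Prais-Winsten feasible GLS.

        The lag-1 autocorrelation is estimated from the current residuals
        as the autocovariance ratio ``sum(e_t e_{t-1}) / sum(e_t^2)``
        (``rho_estimator="regression"`` selects the lagged-regression
        slope variant, which differs at O(1/N)); the data are then
        quasi-differenced, keeping a sqrt(1-rho^2)-scaled first row, and
        the cycle repeats until two successive rho estimates agree within
        ``tol``.  Hitting ``max_iter``, an oscillation among the last
        four iterates, or |rho| >= 1 flags non-convergence.
        """
        return self._iterated_gls("PW", False, tol, max_iter, rho_estimator)

    def fit_cochrane_orcutt(
        self,
        tol: float = 1e-6,
        max_iter: int = 100,
        rho_estimator: str = "autocov",
    ) -> ITSResults:
        """Cochrane-Orcutt variant of the iterated GLS (drops observation 1)."""
        return self._iterated_gls("CO", True, tol, max_iter, rho_estimator)

    # -- likelihood methods ------------------------------------------------

    def _optimize_rho(self, objective) -> tuple[float, bool]:
        res = optimize.minimize_scalar(
            lambda r: -objective(r),
            bounds=(-_RHO_BOUND, _RHO_BOUND),
            method="bounded",
            options={"xatol": 1e-6},
        )
        rho = float(res.x)
        ok = bool(res.success) and abs(rho) < _RHO_BOUND - _BOUNDARY_TOL
        return rho, ok

    def fit_reml(self, satterthwaite: bool = False, fix_rho=None) -> ITSResults:
        """Restricted maximum likelihood under AR(1) error covariance.

        The restricted log-likelihood, profiled over beta (GLS) and the
        marginal error variance, is maximised over rho by bounded scalar
        search on (-0.999, 0.999); an optimum within 1e-3 of the boundary
        is declared non-converged.  ``satterthwaite=True`` additionally
        computes per-coefficient Satterthwaite degrees of freedom
        (floored at 2); otherwise ``df = N - 4``.  ``fix_rho`` skips the
        optimisation and fits GLS at a known autocorrelation.
        """
        X, y = self.X, self.y
        n = self.design.n_points
        if fix_rho is not None:
            rho, ok = float(fix_rho), True
        else:
            rho, ok = self._optimize_rho(lambda r: reml_profile_loglik(y, X, r))
        beta, rss_T, XtX = _gls_at_rho(y, X, rho)
        one_m = 1.0 - rho * rho
        sigma2_marg = rss_T / one_m / (n - 4)
        cov = sigma2_marg * inv(XtX / one_m)
        bse = np.sqrt(np.diag(cov))
        df = np.full(4, n - 4.0)
        flags = np.zeros(4, dtype=bool)
        method = "REML"
        if satterthwaite:
            method = "REML-Satt"
            if ok:
                for i in range(4):
                    df[i], flags[i] = satterthwaite_df(
                        y, X, rho, sigma2_marg, i, vary_rho=fix_rho is None
                    )
        return ITSResults(
            method,
            self,
            beta,
            bse,
            df,
            rho,
            sigma2_marg * one_m,
            converged=ok,
            df_flags=flags,
        )

    def fit_arima(self, compute_se: bool = True, df: str = "t") -> ITSResults:
        """Exact Gaussian ML for the regression with stationary AR(1) errors.

        rho is found by bounded search on the profiled likelihood; the
        coefficient SEs come from the inverse observed information (full
        finite-difference Hessian over beta, rho and the marginal
        variance), so they reflect the uncertainty in the autocorrelation
        estimate.  ``df="t"`` uses a t(N-4) reference for intervals,
        ``df="normal"`` the normal reference.  ``compute_se=False`` skips
        the Hessian and reports GLS-style SEs (useful when only the point
        estimates are needed).
        """
        X, y = self.X, self.y
        n = self.design.n_points
        rho, ok = self._optimize_rho(lambda r: arima_profile_loglik(y, X, r))
        beta, rss_T, XtX = _gls_at_rho(y, X, rho)
        one_m = 1.0 - rho * rho
        sigma2_marg = max(rss_T / one_m / n, 1e-300)
        df_val = n - 4.0 if df == "t" else np.inf
        cov_gls = (rss_T / one_m / (n - 4)) * inv(XtX / one_m)
        bse = np.sqrt(np.diag(cov_gls))
        if compute_se and ok:
            theta = np.concatenate([beta, [rho, sigma2_marg]])

            def negll(th):
                r, s2 = th[4], th[5]
                if abs(r) >= 1.0 or s2 <= 0.0:
                    return 1e12
                return -arima_loglik(y, X, th[:4], r, s2)

            # degenerate fits can overflow the likelihood here; the
            # finite/positivity check below rejects them
            with np.errstate(all="ignore"):
                H = _fd_hessian(negll, theta)
            try:
                covH = inv(H)
                d = np.diag(covH)[:4]
                if np.all(np.isfinite(d)) and np.all(d > 0):
                    bse = np.sqrt(d)
                else:
                    ok = False
            except np.linalg.LinAlgError:
                ok = False
        return ITSResults(
            "ARIMA", self, beta, bse, df_val, rho, sigma2_marg * one_m, converged=ok
        )


# ---------------------------------------------------------------------------
# functional wrappers (series in, FitResult out) and the method registry
# ---------------------------------------------------------------------------


def fit_ols(series: TimeSeries) -> ITSResults:
    return SegmentedITS.from_series(series).fit_ols()


def fit_newey_west(series: TimeSeries, lag: int = 1) -> ITSResults:
    return SegmentedITS.from_series(series).fit_newey_west(lag=lag)


def fit_prais_winsten(
    series: TimeSeries, tol: float = 1e-6, max_iter: int = 100, **kw
) -> ITSResults:
    return SegmentedITS.from_series(series).fit_prais_winsten(
        tol=tol, max_iter=max_iter, **kw
    )


def fit_cochrane_orcutt(series: TimeSeries, **kw) -> ITSResults:
    return SegmentedITS.from_series(series).fit_cochrane_orcutt(**kw)


def fit_reml_ar1(series: TimeSeries, satterthwaite: bool = False, **kw) -> ITSResults:
    return SegmentedITS.from_series(series).fit_reml(satterthwaite=satterthwaite, **kw)


def fit_arima_ml(series: TimeSeries, **kw) -> ITSResults:
    return SegmentedITS.from_series(series).fit_arima(**kw)


#: Fitters keyed by their method labels.
METHODS = {
    "OLS": SegmentedITS.fit_ols,
    "NW": SegmentedITS.fit_newey_west,
    "PW": SegmentedITS.fit_prais_winsten,
    "REML": SegmentedITS.fit_reml,
    "REML-Satt": lambda m, **kw: SegmentedITS.fit_reml(m, satterthwaite=True, **kw),
    "ARIMA": SegmentedITS.fit_arima,
}


# ---------------------------------------------------------------------------
# vectorised OLS across repetitions (used by the Monte-Carlo engine)
# ---------------------------------------------------------------------------


def batch_ols(Y: np.ndarray, design: ITSDesign):
    """OLS across the rows of an ``(n_reps, N)`` outcome matrix.

    Returns ``(coefs, ses, resid)`` with shapes (n_reps, 4), (n_reps, 4)
    and (n_reps, N).  Row r reproduces ``SegmentedITS(Y[r]).fit_ols()``.
    """
    X = np.asarray(build_design_matrix(design))
    n = design.n_points
    XtX_inv = inv(X.T @ X)
    P = XtX_inv @ X.T
    B = Y @ P.T
    R = Y - B @ X.T
    sigma2 = np.einsum("ij,ij->i", R, R) / (n - 4)
    S = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    return B, S, R
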