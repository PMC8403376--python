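"""Monte-Carlo performance measures with their Monte-Carlo standard errors.

Conventions follow the standard simulation-study methodology (Morris,
White & Crowther): bias is the mean estimate minus truth, empirical SE
the across-repetition standard deviation, model-based SE the root mean
of the squared reported SEs, coverage the fraction of nominal confidence
intervals containing truth, and power the fraction excluding zero.  Each
measure carries its MCSE so that simulation noise is visible next to the
estimate.

Non-converged repetitions are excluded from both the numerator and the
denominator of every measure by default (``denominator="converged"``)
and reported separately as a convergence fraction; the alternative
``denominator="all"`` keeps non-converged repetitions in coverage/power
denominators (counting their intervals as missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParams
from . import dwtest as _dw

__all__ = [
    "ScenarioResult",
    "PerformanceSummary",
    "bias",
    "empirical_se",
    "model_se",
    "coverage",
    "power",
    "convergence_fraction",
    "summarize_scenario",
]

_ESTIMAND_INDEX = {"beta2": 2, "beta3": 3}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def bias(estimates, truth: float) -> tuple[float, float]:
    """Mean estimate minus truth, with MCSE = empSE / sqrt(n)."""
    x = np.asarray(estimates, dtype=float)
    _require(x.size >= 2, "bias needs at least 2 estimates")
    sd = float(np.std(x, ddof=1))
    return float(np.mean(x) - truth), sd / np.sqrt(x.size)


def empirical_se(estimates) -> tuple[float, float]:
    """Across-repetition SD (ddof=1), with MCSE = sd / sqrt(2(n-1))."""
    x = np.asarray(estimates, dtype=float)
    _require(x.size >= 2, "empirical SE needs at least 2 estimates")
    sd = float(np.std(x, ddof=1))
    return sd, sd / np.sqrt(2.0 * (x.size - 1))


def model_se(se_values) -> float:
    """Root mean square of the model-reported SEs."""
    s = np.asarray(se_values, dtype=float)
    _require(s.size >= 1, "model SE needs at least 1 value")
    return float(np.sqrt(np.mean(s**2)))


def _model_se_mcse(se_values) -> float:
    s = np.asarray(se_values, dtype=float) ** 2
    if s.size < 2:
        return np.nan
    m = model_se(np.sqrt(s))
    if m == 0.0:
        return 0.0
    return float(np.sqrt(np.var(s, ddof=1) / s.size) / (2.0 * m))


def _proportion(hits: np.ndarray) -> tuple[float, float]:
    n = hits.size
    p = float(np.mean(hits))
    return p, float(np.sqrt(p * (1.0 - p) / n))


def coverage(ci_low, ci_high, truth: float) -> tuple[float, float]:
    """Fraction of intervals containing truth, with binomial MCSE."""
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    _require(lo.size >= 1 and lo.size == hi.size, "need matching CI bounds")
    return _proportion((lo <= truth) & (truth <= hi))


def power(ci_low, ci_high) -> tuple[float, float]:
    """Fraction of intervals excluding zero, with binomial MCSE."""
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    _require(lo.size >= 1 and lo.size == hi.size, "need matching CI bounds")
    return _proportion((lo > 0.0) | (hi < 0.0))


def convergence_fraction(flags) -> float:
    """Converged count over all repetitions."""
    f = np.asarray(flags, dtype=bool)
    return float(np.mean(f)) if f.size else np.nan


@dataclass
class MethodReps:
    """Per-repetition outputs of one method in one scenario.

    Arrays are aligned over repetitions; ``estimates``/``ses``/CI bounds
    have one column per tracked estimand (beta2, beta3).
    """

    estimates: np.ndarray  # (n_reps, 2)
    ses: np.ndarray  # (n_reps, 2)
    ci_low: np.ndarray  # (n_reps, 2)
    ci_high: np.ndarray  # (n_reps, 2)
    rho_hat: np.ndarray  # (n_reps,)
    converged: np.ndarray  # (n_reps,) bool


@dataclass
class ScenarioResult:
    """All per-repetition outputs of one scenario (never silently dropped).

    ``dw_outcomes`` holds the Durbin-Watson classification of each
    repetition's segmented-OLS residuals (the DW test is a property of
    the series, not of a fitting method).
    """

    scenario_id: str
    n_reps: int
    methods: dict[str, MethodReps] = field(default_factory=dict)
    dw_outcomes: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, m in self.methods.items():
            if len(m.converged) != self.n_reps:
                raise ValueError(f"method {name!r} arrays do not span n_reps")


@dataclass
class PerformanceSummary:
    """Tidy per-scenario performance table.

    ``table`` has one row per (method, estimand, measure) with columns
    value and mcse; ``convergence`` maps method -> converged fraction;
    ``dw_fractions`` maps DW outcome -> fraction of repetitions.
    """

    scenario_id: str
    table: pd.DataFrame
    convergence: dict[str, float]
    dw_fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Single tidy frame, directly plottable / writable to CSV."""
        rows = [self.table.assign(scenario_id=self.scenario_id)]
        conv = pd.DataFrame(
            {
                "method": list(self.convergence),
                "estimand": "",
                "measure": "convergence",
                "value": list(self.convergence.values()),
                "mcse": np.nan,
                "flag": "",
                "scenario_id": self.scenario_id,
            }
        )
        rows.append(conv)
        if self.dw_fractions:
            dw = pd.DataFrame(
                {
                    "method": "DW",
                    "estimand": "",
                    "measure": list(self.dw_fractions),
                    "value": list(self.dw_fractions.values()),
                    "mcse": np.nan,
                    "flag": "",
                    "scenario_id": self.scenario_id,
                }
            )
            rows.append(dw)
        return pd.concat(rows, ignore_index=True)


def summarize_scenario(
    result: ScenarioResult,
    truth: ModelParams,
    denominator: str = "converged",
) -> PerformanceSummary:
    """Assemble bias/empSE/modSE/ratio/coverage/power (+ rho bias) per method.

    Power rows are flagged ``"approximate"`` when the same method's
    coverage in the scenario is below 90%, since power read off an
    uncalibrated interval overstates or understates the true probability
    of detection.
    """
    if denominator not in ("converged", "all"):
        raise ValueError("denominator must be 'converged' or 'all'")
    truths = {"beta2": truth.beta2, "beta3": truth.beta3}
    rows = []
    convergence = {}
    for name, m in result.methods.items():
        keep = m.converged.astype(bool)
        convergence[name] = convergence_fraction(keep)
        n_all = result.n_reps
        for col, estimand in enumerate(("beta2", "beta3")):
            est = m.estimates[keep, col]
            ses = m.ses[keep, col]
            lo = m.ci_low[keep, col]
            hi = m.ci_high[keep, col]
            if est.size < 2:
                continue
            b, b_m = bias(est, truths[estimand])
            e, e_m = empirical_se(est)
            mse = model_se(ses)
            mse_m = _model_se_mcse(ses)
            ratio = mse / e if e > 0 else np.nan
            ratio_m = (
                ratio * np.sqrt((mse_m / mse) ** 2 + (e_m / e) ** 2)
                if e > 0 and mse > 0
                else np.nan
            )
            cov, cov_m = coverage(lo, hi, truths[estimand])
            pw, pw_m = power(lo, hi)
            if denominator == "all":
                scale = est.size / n_all
                cov, cov_m = cov * scale, cov_m * scale
                pw, pw_m = pw * scale, pw_m * scale
            flag = "approximate" if cov < 0.90 else ""
            rows += [
                (name, estimand, "bias", b, b_m, ""),
                (name, estimand, "empirical_se", e, e_m, ""),
                (name, estimand, "model_se", mse, mse_m, ""),
                (name, estimand, "se_ratio", ratio, ratio_m, ""),
                (name, estimand, "coverage", cov, cov_m, ""),
                (name, estimand, "power", pw, pw_m, flag),
            ]
        rho = m.rho_hat[keep]
        rho = rho[np.isfinite(rho)]
        if rho.size >= 2:
            b, b_m = bias(rho, truth.rho)
            e, e_m = empirical_se(rho)
            rows += [
                (name, "rho", "bias", b, b_m, ""),
                (name, "rho", "empirical_se", e, e_m, ""),
                (name, "rho", "mean", float(np.mean(rho)), b_m, ""),
            ]
    table = pd.DataFrame(
        rows, columns=["method", "estimand", "measure", "value", "mcse", "flag"]
    )
    dw_fractions = {}
    if result.dw_outcomes is not None:
        outcomes = np.asarray(result.dw_outcomes)
        for label in (
            _dw.POSITIVE,
            _dw.NEGATIVE,
            _dw.NO_AUTOCORRELATION,
            _dw.INCONCLUSIVE,
        ):
            dw_fractions[label] = float(np.mean(outcomes == label))
    return PerformanceSummary(result.scenario_id, table, convergence, dw_fractions)
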