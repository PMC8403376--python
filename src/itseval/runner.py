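"""Config-driven orchestration of the Monte-Carlo experiment.

Two entry points:

* :func:`run_experiment` — execute a factorial scenario grid: simulate,
  fit every requested method, run the Durbin-Watson test, and aggregate
  the performance measures.  Per-repetition results are persisted in a
  long-format delimited file per scenario, so measures can be recomputed
  without re-simulation, and an interrupted run resumes from the
  per-scenario checkpoints with identical output.
* :func:`fit_dataset` — multi-method reanalysis of a single observed ITS
  series (one row of estimates/CIs/p-values per method plus the DW
  line), the workflow used when comparing methods on real data.

Randomness: every (scenario, repetition) pair draws from its own
substream of the master seed, so results are independent of execution
order and parallelism degree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import (
    ITSDesign,
    ModelParams,
    Scenario,
    ScenarioGrid,
    enumerate_scenarios,
)
from .estimators import METHODS, SegmentedITS, batch_ols, confidence_interval
from .performance import (
    MethodReps,
    PerformanceSummary,
    ScenarioResult,
    summarize_scenario,
)
from .simulate import SimulationConfig, simulate_matrix
from . import dwtest as _dw

logger = logging.getLogger("itseval")

__all__ = [
    "ExperimentConfig",
    "DatasetAnalysisReport",
    "run_scenario",
    "run_experiment",
    "fit_dataset",
    "dw_outcome_fractions",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ["OLS", "NW", "PW", "REML", "REML-Satt", "ARIMA"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a factorial simulation experiment."""

    grid: ScenarioGrid
    n_reps: int = 1000
    master_seed: int = 20210828
    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    alpha: float = 0.05
    df_convention: str = "t"  # "t" or "normal" for the ARIMA reference
    denominator: str = "converged"
    n_jobs: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100 for MCSE reporting")

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "n_reps": self.n_reps,
            "master_seed": self.master_seed,
            "methods": list(self.methods),
            "alpha": self.alpha,
            "df_convention": self.df_convention,
            "denominator": self.denominator,
            "n_jobs": self.n_jobs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["grid"] = ScenarioGrid.from_dict(d["grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _classify_rows(d: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    d_lower, d_upper = bounds
    out = np.full(d.shape, _dw.INCONCLUSIVE, dtype=object)
    out[d < d_lower] = _dw.POSITIVE
    out[d > 4.0 - d_lower] = _dw.NEGATIVE
    out[(d >= d_upper) & (d <= 4.0 - d_upper)] = _dw.NO_AUTOCORRELATION
    return out


def _ols_reps(Y: np.ndarray, design: ITSDesign, alpha: float) -> MethodReps:
    # vectorised OLS path: identical per-row results to SegmentedITS.fit_ols
    B, S, _ = batch_ols(Y, design)
    df = design.n_points - 4
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    est = B[:, 2:4]
    ses = S[:, 2:4]
    return MethodReps(
        estimates=est,
        ses=ses,
        ci_low=est - tcrit * ses,
        ci_high=est + tcrit * ses,
        rho_hat=np.full(len(B), np.nan),
        converged=np.ones(len(B), dtype=bool),
    )


def run_scenario(
    scenario: Scenario,
    sim: SimulationConfig,
    methods: list[str] = DEFAULT_METHODS,
    alpha: float = 0.05,
    df_convention: str = "t",
) -> ScenarioResult:
    """Simulate one scenario and fit every requested method to every rep.

    Estimator exceptions are caught, logged and counted as
    non-convergence (the repetition is flagged, never dropped).
    """
    params, design = scenario.params, scenario.design
    n_reps = sim.n_reps
    Y = simulate_matrix(params, design, sim, scenario.index)
    _, _, R = batch_ols(Y, design)
    d = _dw.dw_statistic_rows(R)
    bounds = _dw.dw_bounds(design.n_points, 4, alpha)
    outcomes = _classify_rows(d, bounds)

    result = ScenarioResult(scenario.scenario_id, n_reps, dw_outcomes=outcomes)
    for name in methods:
        if name == "OLS":
            result.methods[name] = _ols_reps(Y, design, alpha)
            continue
        est = np.full((n_reps, 2), np.nan)
        ses = np.full((n_reps, 2), np.nan)
        lo = np.full((n_reps, 2), np.nan)
        hi = np.full((n_reps, 2), np.nan)
        rho = np.full(n_reps, np.nan)
        conv = np.zeros(n_reps, dtype=bool)
        kwargs = {}
        if name == "ARIMA" and df_convention == "normal":
            kwargs["df"] = "normal"
        n_failed = 0
        for r in range(n_reps):
            model = SegmentedITS(Y[r], design=design)
            try:
                fit = METHODS[name](model, **kwargs)
            except Exception:  # noqa: BLE001 - tabulated, not fatal
                n_failed += 1
                continue
            est[r] = fit.params[2:4]
            ses[r] = fit.bse[2:4]
            rho[r] = fit.rho
            conv[r] = fit.converged
            if fit.converged:
                for col, idx in enumerate((2, 3)):
                    ci = confidence_interval(fit, idx, level=1 - alpha)
                    lo[r, col] = ci.ci_low
                    hi[r, col] = ci.ci_high
        if n_failed:
            logger.warning(
                "%s: %s raised in %d/%d reps (counted as non-convergence)",
                scenario.scenario_id,
                name,
                n_failed,
                n_reps,
            )
        result.methods[name] = MethodReps(est, ses, lo, hi, rho, conv)
    return result


def scenario_result_to_frame(result: ScenarioResult) -> pd.DataFrame:
    """Long-format per-repetition table (recomputable performance input)."""
    rows = []
    for name, m in result.methods.items():
        for col, estimand in enumerate(("beta2", "beta3")):
            for r in range(result.n_reps):
                rows.append(
                    (
                        result.scenario_id,
                        r,
                        name,
                        estimand,
                        m.estimates[r, col],
                        m.ses[r, col],
                        m.ci_low[r, col],
                        m.ci_high[r, col],
                        bool(m.converged[r]),
                    )
                )
        for r in range(result.n_reps):
            rows.append(
                (
                    result.scenario_id,
                    r,
                    name,
                    "rho",
                    m.rho_hat[r],
                    np.nan,
                    np.nan,
                    np.nan,
                    bool(m.converged[r]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario_id",
            "rep",
            "method",
            "estimand",
            "estimate",
            "se",
            "ci_low",
            "ci_high",
            "converged",
        ],
    )


def _frame_to_scenario(df: pd.DataFrame, dw: pd.DataFrame) -> ScenarioResult:
    scenario_id = df["scenario_id"].iloc[0]
    n_reps = int(df["rep"].max()) + 1
    result = ScenarioResult(
        scenario_id, n_reps, dw_outcomes=dw.sort_values("rep")["outcome"].to_numpy()
    )
    for name, g in df.groupby("method", sort=False):
        arrays = {}
        for estimand, gg in g.groupby("estimand", sort=False):
            arrays[estimand] = gg.sort_values("rep")
        est = np.column_stack(
            [arrays["beta2"]["estimate"], arrays["beta3"]["estimate"]]
        )
        ses = np.column_stack([arrays["beta2"]["se"], arrays["beta3"]["se"]])
        lo = np.column_stack([arrays["beta2"]["ci_low"], arrays["beta3"]["ci_low"]])
        hi = np.column_stack(
            [arrays["beta2"]["ci_high"], arrays["beta3"]["ci_high"]]
        )
        rho = arrays["rho"]["estimate"].to_numpy()
        conv = arrays["beta2"]["converged"].to_numpy(dtype=bool)
        result.methods[name] = MethodReps(est, ses, lo, hi, rho, conv)
    return result


def run_experiment(
    config: ExperimentConfig, out_dir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the factorial experiment; returns (manifest, summary).

    When ``out_dir`` is given, writes ``manifest.csv``, the resolved
    config as ``config.json``, per-scenario raw result files under
    ``raw/`` (the checkpoint unit: existing files are loaded instead of
    recomputed) and the tidy ``summary.csv``.
    """
    scenarios = enumerate_scenarios(config.grid)
    sim = SimulationConfig(n_reps=config.n_reps, master_seed=config.master_seed)
    manifest = pd.DataFrame(
        {
            "scenario_index": [s.index for s in scenarios],
            "scenario_id": [s.scenario_id for s in scenarios],
            "beta2": [s.params.beta2 for s in scenarios],
            "beta3": [s.params.beta3 for s in scenarios],
            "rho": [s.params.rho for s in scenarios],
            "n_points": [s.design.n_points for s in scenarios],
            "rng_stream": [
                f"SeedSequence({config.master_seed}, spawn_key=({s.index}, rep))"
                for s in scenarios
            ],
        }
    )
    raw_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        raw_dir = out_dir / "raw"
        raw_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    def one(s: Scenario) -> PerformanceSummary:
        if raw_dir is not None:
            raw_path = raw_dir / f"scenario_{s.index:04d}.csv"
            dw_path = raw_dir / f"dw_{s.index:04d}.csv"
            if raw_path.exists() and dw_path.exists():
                logger.info("%s: loading checkpoint", s.scenario_id)
                result = _frame_to_scenario(
                    pd.read_csv(raw_path), pd.read_csv(dw_path)
                )
                return summarize_scenario(result, s.params, config.denominator)
        logger.info("%s: running %d reps", s.scenario_id, config.n_reps)
        result = run_scenario(
            s, sim, config.methods, config.alpha, config.df_convention
        )
        if raw_dir is not None:
            scenario_result_to_frame(result).to_csv(raw_path, index=False)
            pd.DataFrame(
                {
                    "scenario_id": s.scenario_id,
                    "rep": np.arange(result.n_reps),
                    "outcome": result.dw_outcomes,
                }
            ).to_csv(dw_path, index=False)
        nonconv = {
            m: 1.0 - float(np.mean(r.converged))
            for m, r in result.methods.items()
        }
        logger.info("%s: non-convergence %s", s.scenario_id, nonconv)
        return summarize_scenario(result, s.params, config.denominator)

    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        summaries = Parallel(n_jobs=config.n_jobs)(
            delayed(one)(s) for s in scenarios
        )
    else:
        summaries = [one(s) for s in scenarios]
    summary = pd.concat([s.to_frame() for s in summaries], ignore_index=True)
    if out_dir is not None:
        summary.to_csv(out_dir / "summary.csv", index=False)
    return manifest, summary


# ---------------------------------------------------------------------------
# fast Durbin-Watson operating characteristics (OLS-only pipeline)
# ---------------------------------------------------------------------------


def dw_outcome_fractions(
    params: ModelParams,
    design: ITSDesign,
    n_reps: int,
    master_seed: int,
    scenario_index: int = 0,
    alpha: float = 0.05,
    two_sided: bool = True,
    split_alpha: bool = False,
) -> dict[str, float]:
    """Fractions of DW outcomes over simulated repetitions of one scenario.

    Simulates, fits segmented OLS, classifies each repetition's DW
    statistic with the symmetric bounds procedure (bounds at ``alpha``
    per direction; ``split_alpha=True`` halves it per tail).  Fully
    vectorised; bit-identical to the per-rep route.
    """
    sim = SimulationConfig(n_reps=n_reps, master_seed=master_seed)
    Y = simulate_matrix(params, design, sim, scenario_index)
    _, _, R = batch_ols(Y, design)
    d = _dw.dw_statistic_rows(R)
    tail = alpha / 2.0 if (two_sided and split_alpha) else alpha
    bounds = _dw.dw_bounds(design.n_points, 4, tail)
    if two_sided:
        outcomes = _classify_rows(d, bounds)
    else:
        outcomes = np.array(
            [_dw.classify_dw(x, bounds, two_sided=False) for x in d], dtype=object
        )
    return {
        label: float(np.mean(outcomes == label))
        for label in (
            _dw.POSITIVE,
            _dw.NEGATIVE,
            _dw.NO_AUTOCORRELATION,
            _dw.INCONCLUSIVE,
        )
    }


# ---------------------------------------------------------------------------
# single-dataset multi-method analysis
# ---------------------------------------------------------------------------


@dataclass
class DatasetAnalysisReport:
    """Multi-method reanalysis of one ITS dataset.

    ``table`` has one row per method with level/slope change estimates,
    confidence intervals, p-values and the method's autocorrelation
    estimate; the Durbin-Watson line is carried separately.
    """

    table: pd.DataFrame
    dw: _dw.DWResult
    design: ITSDesign

    def to_text(self) -> str:
        lines = [
            f"ITS analysis: N = {self.design.n_points}, interruption at "
            f"t = {self.design.interruption_index}",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            (
                f"Durbin-Watson: d = {self.dw.statistic:.2f} "
                f"(dL = {self.dw.d_lower:.2f}, dU = {self.dw.d_upper:.2f}) "
                f"-> {self.dw.classification}"
            ),
        ]
        return "\n".join(lines)


def fit_dataset(
    data,
    interruption_time: float,
    methods: list[str] = DEFAULT_METHODS,
    alpha: float = 0.05,
) -> DatasetAnalysisReport:
    """Fit every requested method to one observed ITS series.

    ``data`` is a two-column table (time, outcome) — a DataFrame, a path
    to a delimited file, or an array — in observation order.  Times are
    mapped to ``t = 1..N``; the interruption index is the first
    observation with ``time >= interruption_time``.  Both segments must
    contain at least 2 points.
    """
    if isinstance(data, (str, Path)):
        data = pd.read_csv(data)
    if isinstance(data, pd.DataFrame):
        if data.shape[1] < 2:
            raise ValueError("expected two columns: time and outcome")
        times = data.iloc[:, 0].to_numpy(dtype=float)
        y = data.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        times, y = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome column contains non-numeric values")
    post = np.nonzero(times >= interruption_time)[0]
    if post.size == 0 or post[0] == 0:
        raise ValueError("interruption_time outside the observed range")
    ti = int(post[0]) + 1  # 1-based index of the first post point
    design = ITSDesign(len(y), ti)
    if design.n_pre < 2 or design.n_post < 2:
        raise ValueError("need at least 2 points on each side of the interruption")
    model = SegmentedITS(y, design=design)
    rows = []
    for name in methods:
        fit = METHODS[name](model)
        row = {"method": name, "converged": fit.converged}
        for label, idx in (("level_change", 2), ("slope_change", 3)):
            if fit.converged:
                ci = confidence_interval(fit, idx, level=1 - alpha)
                row.update(
                    {
                        label: ci.estimate,
                        f"{label}_ci_low": ci.ci_low,
                        f"{label}_ci_high": ci.ci_high,
                        f"{label}_p": ci.p_value,
                    }
                )
            else:
                row.update(
                    {
                        label: fit.params[idx],
                        f"{label}_ci_low": np.nan,
                        f"{label}_ci_high": np.nan,
                        f"{label}_p": np.nan,
                    }
                )
        row["rho_hat"] = fit.rho
        rows.append(row)
    ols = model.fit_ols()
    dw = _dw.dw_test(ols.resid, 4, alpha=alpha)
    return DatasetAnalysisReport(pd.DataFrame(rows), dw, design)
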