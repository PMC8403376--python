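"""Simulation of ITS series with stationary lag-1 autoregressive errors.

Errors follow ``e_t = rho * e_{t-1} + w_t`` with Gaussian white noise
``w_t ~ N(0, sigma2)``.  The first error is drawn from the stationary
distribution by scaling ``w_1`` with ``sqrt(1 / (1 - rho^2))``, so every
error has marginal variance ``sigma2 / (1 - rho^2)`` and the process has
lag-k autocorrelation ``rho**k`` at every time point.

Reproducibility contract: repetition ``r`` of scenario ``s`` under master
seed ``m`` is generated from the dedicated stream
``SeedSequence(m, spawn_key=(s, r))``.  Streams for distinct (scenario,
rep) pairs are statistically independent, so no burn-in between data sets
is needed, and results are bit-identical regardless of execution order or
parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core import ITSDesign, ModelParams, true_mean

__all__ = [
    "TimeSeries",
    "SimulationConfig",
    "generate_ar1_errors",
    "simulate_series",
    "simulate_batch",
    "simulate_matrix",
    "batch_to_frame",
]


@dataclass(frozen=True)
class TimeSeries:
    """One simulated (or observed) ITS outcome vector with its design."""

    y: np.ndarray
    design: ITSDesign

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if y.shape != (self.design.n_points,):
            raise ValueError(
                f"series length {y.shape} does not match design "
                f"n_points={self.design.n_points}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("series contains non-finite values")


@dataclass(frozen=True)
class SimulationConfig:
    """Repetition count and seeding policy for a batch of simulations."""

    n_reps: int
    master_seed: int
    stream_policy: str = "spawn-by-scenario-rep"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def rng(self, scenario_index: int, rep: int) -> np.random.Generator:
        """Dedicated random stream for one repetition of one scenario."""
        ss = np.random.SeedSequence(
            entropy=self.master_seed, spawn_key=(scenario_index, rep)
        )
        return np.random.default_rng(ss)


def _check_ar1_args(rho: float, sigma2: float) -> None:
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")


def _ar1_filter(w: np.ndarray, rho: float) -> np.ndarray:
    # e_t = rho*e_{t-1} + w_t with e_1 = w_1 / sqrt(1-rho^2): scale the
    # first innovation, then run the AR recursion along the last axis.
    w = np.array(w, dtype=float, copy=True)
    w[..., 0] /= np.sqrt(1.0 - rho * rho)
    if rho == 0.0:
        return w
    return lfilter([1.0], [1.0, -rho], w, axis=-1)


def generate_ar1_errors(
    rho: float, sigma2: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) Gaussian error vector of length ``n``.

    Every ``e_t`` has marginal variance ``sigma2 / (1 - rho^2)``; the
    lag-1 autocorrelation of the process is ``rho``.
    """
    _check_ar1_args(rho, sigma2)
    if n < 1:
        raise ValueError("n must be >= 1")
    w = rng.normal(0.0, np.sqrt(sigma2), size=n)
    return _ar1_filter(w, rho)


def simulate_series(
    params: ModelParams, design: ITSDesign, rng: np.random.Generator
) -> TimeSeries:
    """One series: segmented mean plus stationary AR(1) errors."""
    y = true_mean(params, design) + generate_ar1_errors(
        params.rho, params.sigma2, design.n_points, rng
    )
    return TimeSeries(y=y, design=design)


def simulate_matrix(
    params: ModelParams,
    design: ITSDesign,
    config: SimulationConfig,
    scenario_index: int = 0,
) -> np.ndarray:
    """All repetitions of one scenario as an ``(n_reps, N)`` matrix.

    Row ``r`` is bit-identical to ``simulate_series`` run on the stream
    ``config.rng(scenario_index, r)``.
    """
    n = design.n_points
    w = np.empty((config.n_reps, n))
    sd = np.sqrt(params.sigma2)
    for r in range(config.n_reps):
        w[r] = config.rng(scenario_index, r).normal(0.0, sd, size=n)
    return true_mean(params, design) + _ar1_filter(w, params.rho)


def simulate_batch(
    params: ModelParams,
    design: ITSDesign,
    config: SimulationConfig,
    scenario_index: int = 0,
) -> list[TimeSeries]:
    """Independent repetitions of one scenario as ``TimeSeries`` objects."""
    Y = simulate_matrix(params, design, config, scenario_index)
    return [TimeSeries(y=row, design=design) for row in Y]


def batch_to_frame(batch: list[TimeSeries], scenario_id: str = "scenario"):
    """Long-format table (scenario_id, rep, t, y) of a simulated batch."""
    import pandas as pd

    frames = []
    for rep, ts in enumerate(batch):
        frames.append(
            pd.DataFrame(
                {
                    "scenario_id": scenario_id,
                    "rep": rep,
                    "t": ts.design.time,
                    "y": ts.y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
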