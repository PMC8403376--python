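"""Segmented-regression model structure for interrupted time series (ITS).

An ITS design observes a continuous outcome at regularly spaced times
``t = 1, ..., N`` with a single interruption.  The mean model is the
Huitema-McKean segmented linear regression

    Y_t = b0 + b1*t + b2*D_t + b3*(t - T_I)*D_t + e_t,

where ``D_t = 1(t >= T_I)`` indicates the post-interruption segment,
``b2`` is the immediate level change at the interruption and ``b3`` the
change in slope.  Time indexing convention (documented prominently because
it fixes the meaning of ``b2``): the interruption index ``T_I`` is the
*first post-interruption point*, so the slope-change regressor
``(t - T_I)*D_t`` is zero at ``t = T_I`` and increments by one per
post-interruption step.  A midpoint interruption on an even-length series
means ``T_I = N/2 + 1``: exactly ``N/2`` points pre and ``N/2`` post.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import yaml

__all__ = [
    "ITSDesign",
    "ModelParams",
    "ScenarioGrid",
    "Scenario",
    "build_design_matrix",
    "true_mean",
    "enumerate_scenarios",
    "default_scenario_grid",
]


@dataclass(frozen=True)
class ITSDesign:
    """Series length and interruption index of a single-interruption ITS.

    Parameters
    ----------
    n_points : int
        Number of observations ``N`` (>= 5).
    interruption_index : int
        ``T_I``, the 1-based time index of the first post-interruption
        observation; must satisfy ``2 <= T_I <= N``.
    """

    n_points: int
    interruption_index: int

    def __post_init__(self) -> None:
        n, ti = self.n_points, self.interruption_index
        if n < 5:
            raise ValueError(f"n_points must be >= 5, got {n}")
        if not 2 <= ti <= n:
            raise ValueError(f"interruption_index must be in [2, {n}], got {ti}")

    @classmethod
    def midpoint(cls, n_points: int) -> "ITSDesign":
        """Design with an equal pre/post split: ``T_I = N/2 + 1`` (N even)."""
        if n_points % 2:
            raise ValueError("midpoint design requires an even number of points")
        return cls(n_points, n_points // 2 + 1)

    @property
    def time(self) -> np.ndarray:
        """The 1-based time index ``t = 1, ..., N``."""
        return np.arange(1, self.n_points + 1)

    @property
    def n_pre(self) -> int:
        return self.interruption_index - 1

    @property
    def n_post(self) -> int:
        return self.n_points - self.interruption_index + 1


@dataclass(frozen=True)
class ModelParams:
    """Data-generating parameters of the segmented model with AR(1) errors.

    ``beta0``/``beta1`` are the pre-interruption intercept and slope,
    ``beta2``/``beta3`` the level and slope changes, ``rho`` the lag-1
    autocorrelation of the errors (|rho| < 1) and ``sigma2`` the variance
    of the white-noise innovations (>= 0).
    """

    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    rho: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1 for stationarity, got {self.rho}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


@lru_cache(maxsize=256)
def _design_matrix_cached(n: int, ti: int) -> np.ndarray:
    t = np.arange(1, n + 1, dtype=float)
    d = (t >= ti).astype(float)
    X = np.column_stack([np.ones(n), t, d, (t - ti) * d])
    X.setflags(write=False)
    return X


def build_design_matrix(design: ITSDesign) -> np.ndarray:
    """N x 4 design matrix ``[1, t, D_t, (t - T_I) * D_t]``.

    Raises
    ------
    ValueError
        If either segment has fewer than 2 points, which makes the matrix
        rank deficient (the segment slope is then unidentifiable).
    """
    if design.n_pre < 2 or design.n_post < 2:
        raise ValueError(
            "design matrix is rank deficient: need >= 2 points in each "
            f"segment, got {design.n_pre} pre / {design.n_post} post"
        )
    return _design_matrix_cached(design.n_points, design.interruption_index)


def true_mean(params: ModelParams, design: ITSDesign) -> np.ndarray:
    """Deterministic part of the segmented model, ``X @ beta``."""
    return build_design_matrix(design) @ params.beta


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial simulation grid."""

    index: int
    params: ModelParams
    design: ITSDesign

    @property
    def scenario_id(self) -> str:
        p = self.params
        return (
            f"b2={p.beta2:g}_b3={p.beta3:g}_rho={p.rho:g}_n={self.design.n_points}"
        )


@dataclass
class ScenarioGrid:
    """Fully factorial grid of data-generating conditions.

    The default construction (:func:`default_scenario_grid`) is the study
    grid used throughout this package: level changes {0, 0.5, 1, 2}, slope
    changes {0, 0.1}, autocorrelations {0, 0.2, 0.4, 0.6, 0.8}, twenty
    series lengths from 6 to 100, white-noise variance 1 and zero baseline
    intercept/slope — 4 x 2 x 5 x 20 = 800 scenarios.
    """

    level_changes: list[float]
    slope_changes: list[float]
    rhos: list[float]
    lengths: list[int]
    beta0: float = 0.0
    beta1: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("level_changes", "slope_changes", "rhos", "lengths"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"factor list {name!r} is empty")

    @property
    def n_scenarios(self) -> int:
        return (
            len(self.level_changes)
            * len(self.slope_changes)
            * len(self.rhos)
            * len(self.lengths)
        )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "level_change": list(self.level_changes),
            "slope_change": list(self.slope_changes),
            "rho": list(self.rhos),
            "n_points": list(self.lengths),
            "beta0": self.beta0,
            "beta1": self.beta1,
            "sigma2": self.sigma2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioGrid":
        def aslist(x):
            return list(x) if isinstance(x, (list, tuple)) else [x]

        return cls(
            level_changes=[float(v) for v in aslist(d["level_change"])],
            slope_changes=[float(v) for v in aslist(d["slope_change"])],
            rhos=[float(v) for v in aslist(d["rho"])],
            lengths=[int(v) for v in aslist(d["n_points"])],
            beta0=float(d.get("beta0", 0.0)),
            beta1=float(d.get("beta1", 0.0)),
            sigma2=float(d.get("sigma2", 1.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioGrid":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def enumerate_scenarios(grid: ScenarioGrid) -> list[Scenario]:
    """Cartesian product of the grid factors in a fixed, documented order.

    Order: level change (slowest), slope change, rho, series length
    (fastest), each factor in its listed order.  The enumeration is a
    bijection onto the product; ``Scenario.index`` is the position and
    ``Scenario.scenario_id`` a stable human-readable identifier.
    """
    out = []
    prod = itertools.product(
        grid.level_changes, grid.slope_changes, grid.rhos, grid.lengths
    )
    for i, (b2, b3, rho, n) in enumerate(prod):
        params = ModelParams(
            beta0=grid.beta0,
            beta1=grid.beta1,
            beta2=b2,
            beta3=b3,
            rho=rho,
            sigma2=grid.sigma2,
        )
        out.append(Scenario(index=i, params=params, design=ITSDesign.midpoint(n)))
    return out


def default_scenario_grid() -> ScenarioGrid:
    """The 800-cell factorial study grid (see :class:`ScenarioGrid`)."""
    lengths = list(range(6, 21, 2)) + list(range(24, 57, 4)) + [60, 80, 100]
    return ScenarioGrid(
        level_changes=[0.0, 0.5, 1.0, 2.0],
        slope_changes=[0.0, 0.1],
        rhos=[0.0, 0.2, 0.4, 0.6, 0.8],
        lengths=lengths,
    )
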