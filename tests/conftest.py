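import numpy as np
import pytest

from itseval.core import ITSDesign, ModelParams
from itseval.simulate import SimulationConfig, simulate_matrix, simulate_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def one_series(params: ModelParams, design: ITSDesign, seed: int):
    """One reproducible simulated series (rep 0 of its own stream)."""
    return simulate_series(params, design, SimulationConfig(1, seed).rng(0, 0))


def series_matrix(params, design, n_reps, seed, scenario_index=0):
    return simulate_matrix(
        params, design, SimulationConfig(n_reps, seed), scenario_index
    )


@pytest.fixture
def ar_series_10():
    """A fixed 10-point series with moderate autocorrelation."""
    return one_series(
        ModelParams(beta2=1.0, beta3=0.1, rho=0.4), ITSDesign.midpoint(10), seed=7
    )


@pytest.fixture
def ar_series_48():
    return one_series(
        ModelParams(beta2=2.0, beta3=0.1, rho=0.4), ITSDesign.midpoint(48), seed=11
    )
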