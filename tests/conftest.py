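import numpy as np
import pytest

from multiscale_rc import (
    DriftSpec,
    EchoStateNetwork,
    NoiseModel,
    ReservoirConfig,
    separate_noise,
    simulate_sde,
)
from multiscale_rc.experiments import load_config, reservoir_config_from


@pytest.fixture(scope="session")
def eq9_series():
    """Canonical noisy double-well trajectory (b=5, eps=0.3, dt=0.01)."""
    drift = DriftSpec.bistable_1d(b=5.0, c=0.0)
    amp = np.sqrt(2 * 0.3 * 5.0)
    return simulate_sde(drift, amp, 1.5, 0.01, 10000, seed=7)


@pytest.fixture(scope="session")
def example1_config():
    return load_config("example1")


@pytest.fixture(scope="session")
def example1_esn(eq9_series, example1_config):
    """Slow-scale model trained with the shipped double-well fixture."""
    config = reservoir_config_from(example1_config, seed=11)
    esn = EchoStateNetwork(config, n_inputs=1)
    esn.train(eq9_series)
    return esn


@pytest.fixture(scope="session")
def example1_noise(example1_esn, eq9_series):
    _, residual = separate_noise(example1_esn, eq9_series)
    return NoiseModel(mode="empirical", residuals=residual.values, amplification=1.1)


@pytest.fixture()
def small_config():
    """A cheap reservoir for unit tests."""
    return ReservoirConfig(
        n_nodes=120, input_scaling=1.0, degree=4, spectral_radius=0.3,
        leak_rate=0.5, ridge_beta=1e-6, seed=3, washout=20,
    )
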