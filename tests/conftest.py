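import numpy as np
import pytest

from memfusion import SimConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Very small design for fast structural tests (not a calibration run)."""
    return SimConfig.scaled(n_subjects=3, n_pairs=4, grid_shape=(8, 8, 8), n_rois=2, n_sensors=12, seed=7)


@pytest.fixture(scope="session")
def tiny_experiment(tiny_config):
    return simulate_experiment(tiny_config)


@pytest.fixture(scope="session")
def scaled_experiment():
    """The desk-scale profile with the planted 300 ms divergence."""
    return simulate_experiment(SimConfig.scaled(seed=11))
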