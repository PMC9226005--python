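import numpy as np
import pandas as pd
import pytest

from isomirnet.model import ModelConfig, build_model
from isomirnet.simulate import SimulationConfig, simulate_dataset


TINY_MODEL = dict(
    mirna_len=14, site_len=20, n_kernels=3, kernel_len=4, pool_size=2,
    lstm_units_per_direction=3, dense_units=8,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small error-free simulated experiment shared across tests."""
    cfg = SimulationConfig(
        n_mirnas=6, n_transcripts=4, reads_per_pair=12,
        base_error_rate=0.0, seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_predictor():
    """An untrained, very small predictor for fast structural tests."""
    return build_model(ModelConfig(seed=3, **TINY_MODEL))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
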