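import numpy as np
import pytest

from gridtrack import world


@pytest.fixture(scope="session")
def default_config() -> world.WorldConfig:
    return world.WorldConfig()


@pytest.fixture(scope="session")
def noiseless_config() -> world.WorldConfig:
    return world.WorldConfig(rssi_noise_sd=0.0, ou_sigma=0.0)


@pytest.fixture(scope="session")
def grid() -> world.NodeGrid:
    """The study-scale receiver grid: 166 nodes, 40-m triangular, 3-m jitter."""
    return world.generate_grid(spacing=40.0, n_nodes=166, jitter_sd=3.0, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
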