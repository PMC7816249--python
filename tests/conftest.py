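import numpy as np
import pytest

from circuitmig.raster import RasterGrid
from circuitmig.synthetic import SimulationConfig, generate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=5, n_animals=3)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """30x30 km synthetic landscape shared across tests."""
    return generate_landscape(small_config, extent=(0.0, 0.0, 30.0, 30.0), cell_size=1.0)


@pytest.fixture
def uniform_grid():
    return RasterGrid(np.ones((8, 8)))
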