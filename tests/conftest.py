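import numpy as np
import pytest

from pfclust import Region, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_region():
    return Region(0.0, 0.0, 100.0, 100.0)


@pytest.fixture
def fov_region():
    """The in vivo imaging window: 56 μm sagittal × molecular layer."""
    return Region(0.0, 0.0, 56.0, 150.0)


@pytest.fixture
def base_config():
    return SimulationConfig(seed=2024)
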