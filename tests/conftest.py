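import numpy as np
import pytest

from deepsea_exposure import Grid, regular_grid


@pytest.fixture
def small_grid() -> Grid:
    """24x24 cells over a CCZ-sized box (1-degree spacing)."""
    return regular_grid(24, 24, lat_range=(-12.0, 11.0),
                        lon_range=(-150.0, -127.0))


@pytest.fixture
def tiny_grid() -> Grid:
    return regular_grid(4, 5, lat_range=(0.0, 3.0), lon_range=(10.0, 14.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
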