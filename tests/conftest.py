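import numpy as np
import pandas as pd
import pytest

from yieldgap.io_core import GridTransform, RasterGrid
from yieldgap.synthetic import (
    SimulationConfig,
    generate_climate_fields,
    generate_counties,
    generate_determinant_panel,
)


@pytest.fixture(scope="session")
def small_config():
    """5x5 counties, 4 cells per side — big enough for spatial structure,
    small enough for brute-force oracles."""
    return SimulationConfig(
        seed=42, n_county_x=5, n_county_y=5, cells_per_county_side=4, n_municipal_districts=4
    )


@pytest.fixture(scope="session")
def small_counties(small_config):
    return generate_counties(small_config)


@pytest.fixture(scope="session")
def small_fields(small_config, small_counties):
    return generate_climate_fields(small_config, small_counties)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_counties(default_config):
    return generate_counties(default_config)


@pytest.fixture(scope="session")
def default_fields(default_config, default_counties):
    return generate_climate_fields(default_config, default_counties)


@pytest.fixture(scope="session")
def default_panel(default_config, default_counties):
    return generate_determinant_panel(default_config, default_counties)


@pytest.fixture
def unit_transform():
    return GridTransform(x0=0.0, y0=10.0, cell_size=1.0)


def make_grid(values, transform=None, **kw):
    values = np.asarray(values, dtype=float)
    if transform is None:
        transform = GridTransform(x0=0.0, y0=float(values.shape[0]), cell_size=1.0)
    return RasterGrid(values=values, transform=transform, **kw)


@pytest.fixture
def grid_factory():
    return make_grid
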