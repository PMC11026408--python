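import numpy as np
import pytest

import climspeed as cs


@pytest.fixture
def small_grid() -> cs.Grid:
    """10 x 20 global grid, cell centers off the poles."""
    return cs.regular_grid(10, 20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_ensemble():
    """Two identical noise-free members with a uniform -0.05 K/yr trend
    and a 0.01 K/km meridional climatological gradient (true speed 5 km/yr)."""
    cfg = cs.SyntheticConfig(
        nlat=24, nlon=36, trend=-0.05, meridional_gradient=0.01,
        noise_sigma=0.0, n_members=2, n_years=20, seed=7,
    )
    return cs.generate_ensemble(cfg)


def make_cube(grid: cs.Grid, years: np.ndarray, values: np.ndarray, member="m0") -> cs.TemperatureCube:
    return cs.TemperatureCube(grid, years, values, member)
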