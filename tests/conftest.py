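import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import refugia as rf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return rf.SyntheticConfig(grid_rows=20, grid_cols=30, seed=42)


@pytest.fixture(scope="session")
def small_climate(small_config):
    return rf.make_climate_grid(small_config)


@pytest.fixture(scope="session")
def small_bioclim(small_climate):
    return rf.derive_bioclim(small_climate)


@pytest.fixture(scope="session")
def smooth_niche():
    return rf.NicheFunction({"DD5": (1200.0, 450.0), "MAP": (550.0, 250.0)})


@pytest.fixture(scope="session")
def toy_normals():
    """A continental mid-latitude monthly-normal profile."""
    return rf.MonthlyNormals(
        tmin=[-15, -13, -8, -2, 3, 8, 11, 10, 5, 0, -7, -13],
        tmax=[-5, -3, 2, 8, 15, 20, 23, 22, 16, 9, 0, -4],
        precip=[30, 25, 30, 35, 50, 70, 80, 70, 50, 40, 35, 30],
    )


@pytest.fixture(scope="session")
def random_grid():
    rng = np.random.default_rng(7)
    def make(shape=(12, 15), seed=None, low=0.0, high=1.0):
        r = rng if seed is None else np.random.default_rng(seed)
        return rf.RasterGrid(r.uniform(low, high, shape), x0=-100, y0=55,
                             cell_size=0.5)
    return make
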