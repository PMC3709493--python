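import numpy as np
import pytest

from reefshed import hydrology as hyd
from reefshed import lulcc
from reefshed import synthetic as syn


@pytest.fixture(scope="session")
def stack16():
    """A 16×16 synthetic watershed shared by read-only tests."""
    return syn.generate_watershed(16, 16, 500.0, seed=7, forest_fraction=0.4)


@pytest.fixture(scope="session")
def climate10(stack16):
    """Ten years of present-day forcing on the shared stack."""
    return syn.generate_climate(stack16, syn.SyntheticClimateParams(n_years=10, seed=3))


@pytest.fixture(scope="session")
def cover_table():
    return lulcc.CoverFactorTable()


@pytest.fixture(scope="session")
def kc16(stack16, cover_table):
    return lulcc.to_crop_factor(stack16.landcover, cover_table)


@pytest.fixture(scope="session")
def sim16(stack16, climate10, kc16):
    return hyd.simulate(stack16, climate10, kc16,
                        hyd.HydroParams(direct_fraction=0.4, gw_recession=0.3))


def random_filled_dem(seed: int, n: int = 6) -> np.ndarray:
    """Small random DEM run through depression filling (oracle fixtures)."""
    from reefshed import terrain

    rng = np.random.default_rng(seed)
    return terrain.fill_depressions(rng.uniform(0.0, 10.0, size=(n, n)))
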