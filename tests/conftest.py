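import numpy as np
import pytest
import shapely

from parkequity.config import CityConfig, ExposureParams
from parkequity.exposure import RasterField
from parkequity.parkgeom import ParkRecord, Tract
from parkequity.privilege import DemographicTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def unit_tract():
    return Tract("t0", shapely.box(0, 0, 1, 1), "city")


def small_city_config(**overrides) -> CityConfig:
    """A cheap city: 8x8 tracts, one exposure variable, coarse raster."""
    defaults = dict(
        n_tracts_x=8,
        n_tracts_y=8,
        n_parks=12,
        raster_resolution=0.5,
        exposure_params={"no2": ExposureParams(12.0, -1.0, 1.0, "ppb")},
        n_scenes=4,
        seed=0,
    )
    defaults.update(overrides)
    return CityConfig(**defaults)


@pytest.fixture
def small_config():
    return small_city_config()


def make_table(tract_id, all_counts, black=None, white=None, area="city"):
    all_counts = np.asarray(all_counts)
    if black is None:
        black = np.zeros_like(all_counts)
    if white is None:
        white = np.zeros_like(all_counts)
    return DemographicTable(
        tract_id=tract_id,
        urban_area_id=area,
        bracket_counts_all=all_counts,
        bracket_counts_black=black,
        bracket_counts_white_nh=white,
        race_white_nh=int(np.sum(white)),
        race_black=int(np.sum(black)),
        race_total=int(np.sum(all_counts)),
    )


def constant_raster(value, n=4, cell=1.0, variable="x"):
    return RasterField(np.full((n, n), float(value)), 0.0, n * cell, cell, variable)
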