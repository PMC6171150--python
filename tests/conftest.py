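import numpy as np
import pandas as pd
import pytest

from ptarmigan_rsf.rasters import Grid, LandscapeStack
from ptarmigan_rsf.survey import TransectLine
from ptarmigan_rsf import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_landscape():
    """Constant elevation/timberline, one vegetation class."""
    grid = Grid(xll=0.0, yll=0.0, cell_size=30.0, nrows=32, ncols=32)
    return LandscapeStack(
        vegetation=np.full((32, 32), 17, dtype=int),
        elevation=np.full((32, 32), 900.0),
        timberline=np.full((32, 32), 875.0),
        grid=grid,
    )


@pytest.fixture
def small_landscape():
    return syn.make_landscape(seed=1, rows=64, cols=64)


@pytest.fixture
def four_km_transect():
    return TransectLine(id="T4", area_id="A1", vertices=((0.0, 0.0), (4000.0, 0.0)))


@pytest.fixture
def toy_observations():
    """Five observations on a straight 1-km transect: computed distances
    {50, 150, 210, 90, 100} with reported-distance deviations
    {0, 0, 0, 40, 10}; hand enumeration gives 3 retained, 1 removed by
    the buffer rule, 1 by the deviation rule."""
    dist = [50.0, 150.0, 210.0, 90.0, 100.0]
    dev = [0.0, 0.0, 0.0, 40.0, 10.0]
    return pd.DataFrame(
        {
            "survey_id": ["S1"] * 5,
            "transect_id": ["T1"] * 5,
            "area_id": ["A1"] * 5,
            "year": [2014] * 5,
            "x": [100.0, 200.0, 300.0, 400.0, 500.0],
            "y": dist,
            "reported_perp_distance_m": [d + e for d, e in zip(dist, dev)],
        }
    )


@pytest.fixture
def toy_transect():
    return TransectLine(id="T1", area_id="A1", vertices=((0.0, 0.0), (1000.0, 0.0)))
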