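import numpy as np
import pandas as pd
import pytest
import xarray as xr

from anen_aq import SyntheticConfig
from anen_aq.constants import INIT_DIM, LAT_DIM, LEAD_DIM, LON_DIM, VALID_DIM
from anen_aq.synthetic import simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial synthetic study: 120 days, 6 leads, 3x3 grid."""
    cfg = SyntheticConfig(n_days=120, n_lead=6, grid_shape=(3, 3), seed=7)
    forecasts, truth, events = simulate(cfg)
    return cfg, forecasts, truth, events


def make_cube(values, init_times, lead_hours, lats, lons, var="pm10", units="ug m-3"):
    """Hand-built forecast cube for micro-tests."""
    da = xr.DataArray(
        np.asarray(values, dtype=float),
        dims=(INIT_DIM, LEAD_DIM, LAT_DIM, LON_DIM),
        coords={
            INIT_DIM: pd.DatetimeIndex(init_times),
            LEAD_DIM: np.asarray(lead_hours, dtype="int64"),
            LAT_DIM: np.asarray(lats, dtype=float),
            LON_DIM: np.asarray(lons, dtype=float),
        },
    )
    da.attrs["units"] = units
    return xr.Dataset({var: da})


def make_series(values, valid_times, lats, lons, var="pm10", units="ug m-3"):
    """Hand-built analysis series for micro-tests."""
    da = xr.DataArray(
        np.asarray(values, dtype=float),
        dims=(VALID_DIM, LAT_DIM, LON_DIM),
        coords={
            VALID_DIM: pd.DatetimeIndex(valid_times),
            LAT_DIM: np.asarray(lats, dtype=float),
            LON_DIM: np.asarray(lons, dtype=float),
        },
    )
    da.attrs["units"] = units
    return xr.Dataset({var: da})
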