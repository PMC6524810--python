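"""Shared fixtures: small synthetic scenarios and in-memory effort grids."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import effortseason as es
from effortseason import ingest


def make_effort(values: np.ndarray, gears=("trawlers",),
                start_year: int = 2015,
                lat=None, lon=None) -> xr.DataArray:
    """Build a monthly effort DataArray from raw values.

    ``values`` has shape (n_gears, n_months, n_lat, n_lon) in per-day
    units; months run consecutively from January of ``start_year``.
    """
    values = np.asarray(values, dtype=float)
    ng, nm, nlat, nlon = values.shape
    months = pd.period_range(f"{start_year}-01", periods=nm, freq="M")
    if lat is None:
        lat = np.arange(nlat) + 0.5
    if lon is None:
        lon = np.arange(nlon) + 0.5
    return xr.DataArray(
        values,
        dims=("gear", "month", "lat", "lon"),
        coords={
            "gear": list(gears),
            "month": [m.to_timestamp() for m in months],
            "lat": lat,
            "lon": lon,
            "days_in_month": ("month",
                             np.array([m.days_in_month for m in months], float)),
        },
        name="effort_per_day",
        attrs={"resolution_deg": 1.0},
    )


def small_moratorium() -> es.Moratorium:
    return es.Moratorium(
        region=[(100.0, 12.0), (112.0, 12.0), (112.0, 24.0), (100.0, 24.0)],
        windows=[("2015-05-16", "2015-09-16"),
                 ("2016-05-16", "2016-09-16"),
                 ("2017-05-01", "2017-09-16")],
        factor=0.1,
    )


def small_scenario(**kw) -> es.Scenario:
    """A 24x24-cell analogue of the default scenario (fast to generate)."""
    defaults = dict(lon_min=100.0, lon_max=124.0, lat_min=0.0, lat_max=24.0,
                    mean_total_effort=200.0, moratorium=small_moratorium(),
                    seed=0)
    defaults.update(kw)
    return es.Scenario(**defaults)


@pytest.fixture(scope="session")
def poisson_data():
    """One Poisson realization of the small scenario, shared across tests."""
    return es.generate_parametric(small_scenario(noise="poisson", seed=1))


@pytest.fixture(scope="session")
def poisson_effort(poisson_data):
    """1-degree monthly effort grid of the shared realization, post-split."""
    vessels = es.split_purse_seiners(
        ingest.read_vessel_table(poisson_data.vessels))
    daily = es.rasterize_daily(poisson_data.records, es.GridSpec(1.0),
                               vessels=vessels)
    return es.monthly_aggregate(daily, es.GridSpec(1.0))
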