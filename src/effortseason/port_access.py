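"""Distance-to-port interpolation and effort-weighted variability profiles.

Each analysis cell gets a distance to the nearest port, interpolated
bilinearly at its center from a fine-resolution raster.  The local
relative standard deviation of monthly effort is then averaged within
contiguous distance bins, weighted by the cells' mean effort; bins
holding less than a small fraction (0.1% by default) of the gear's
global annual effort are flagged as discarded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .grids import GridSpec

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_KM = 75.0
DEFAULT_DISCARD_FRAC = 0.001


def distance_raster_from_netcdf(path) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    return ds["distance_km"]


def distance_raster_from_csv(path) -> xr.DataArray:
    """Read a `lon,lat,distance_km` table into a (lat, lon) raster."""
    df = pd.read_csv(path)
    pivot = df.pivot(index="lat", columns="lon", values="distance_km").sort_index()
    return xr.DataArray(
        pivot.values,
        dims=("lat", "lon"),
        coords={"lat": pivot.index.values, "lon": pivot.columns.values},
        name="distance_km",
    )


def interpolate_raster(raster: xr.DataArray, lon, lat) -> np.ndarray:
    """Bilinear interpolation of a (lat, lon) raster at arbitrary points.

    Invalid raster nodes (NaN) are handled by renormalizing over the
    valid neighbors; a point whose four surrounding nodes are all
    invalid, or which falls outside the raster extent, yields NaN.
    """
    lats = raster["lat"].values
    lons = raster["lon"].values
    vals = raster.values.astype(float)
    valid = np.isfinite(vals)
    filled = np.where(valid, vals, 0.0)
    pts = np.column_stack([np.asarray(lat, dtype=float).ravel(),
                           np.asarray(lon, dtype=float).ravel()])
    f_val = RegularGridInterpolator((lats, lons), filled,
                                    bounds_error=False, fill_value=np.nan)
    f_w = RegularGridInterpolator((lats, lons), valid.astype(float),
                                  bounds_error=False, fill_value=np.nan)
    num = f_val(pts)
    w = f_w(pts)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(w > 0, num / w, np.nan)
    return out.reshape(np.shape(lon))


def distance_at_cells(raster: xr.DataArray, grid: GridSpec,
                      lat: np.ndarray | None = None,
                      lon: np.ndarray | None = None) -> xr.DataArray:
    """Distance (km) interpolated at cell centers of ``grid``.

    ``lat``/``lon`` restrict the output to given center coordinates
    (e.g. those of an effort grid); default is the full global grid.
    Cells outside the raster extent or with no valid neighbor are NaN.
    """
    if lat is None:
        lat = grid.lat_centers
    if lon is None:
        lon = grid.lon_centers
    lon2, lat2 = np.meshgrid(lon, lat)
    d = interpolate_raster(raster, lon2, lat2)
    return xr.DataArray(d, dims=("lat", "lon"),
                        coords={"lat": lat, "lon": lon},
                        name="distance_km")


def binned_variability(local_sd: xr.DataArray,
                       mean_effort: xr.DataArray,
                       distances: xr.DataArray,
                       bin_width_km: float = DEFAULT_BIN_WIDTH_KM,
                       discard_frac: float = DEFAULT_DISCARD_FRAC) -> pd.DataFrame:
    """Effort-weighted mean local relative sd per distance-to-port bin.

    For bin b: ``Σ_{(i,j)∈b} sd(i,j)·ē(i,j) / Σ_{(i,j)∈b} ē(i,j)`` where
    ``ē`` is the cell's mean effort (the weight).  Bins whose summed
    effort is below ``discard_frac`` of the global total are flagged
    ``retained=False`` (values still computed).  Inputs are per-gear
    (lat, lon) layers on a common grid.

    Returns a frame ``bin_lo_km, bin_hi_km, weighted_sd, effort_share,
    n_cells, retained`` covering contiguous half-open bins from 0.
    """
    sd = np.asarray(local_sd.values, dtype=float).ravel()
    w = np.asarray(mean_effort.values, dtype=float).ravel()
    d = np.asarray(distances.values, dtype=float).ravel()
    total_effort = np.nansum(np.where(w > 0, w, 0.0))
    valid = np.isfinite(sd) & np.isfinite(d) & (w > 0)
    sd, w, d = sd[valid], w[valid], d[valid]
    if total_effort <= 0:
        raise ValueError("no effort; profile undefined")

    max_d = d.max() if d.size else 0.0
    n_bins = max(1, int(np.floor(max_d / bin_width_km)) + 1)
    edges = bin_width_km * np.arange(n_bins + 1)
    idx = np.minimum((d // bin_width_km).astype(int), n_bins - 1)

    rows = []
    for b in range(n_bins):
        sel = idx == b
        wb = w[sel]
        eff = wb.sum()
        share = eff / total_effort
        wsd = float((sd[sel] * wb).sum() / eff) if eff > 0 else np.nan
        rows.append({
            "bin_lo_km": edges[b],
            "bin_hi_km": edges[b + 1],
            "weighted_sd": wsd,
            "effort_share": share,
            "n_cells": int(sel.sum()),
            "retained": bool(share >= discard_frac),
        })
    return pd.DataFrame(rows)


def gear_profile(effort: xr.DataArray, gear: str,
                 distances: xr.DataArray,
                 bin_width_km: float = DEFAULT_BIN_WIDTH_KM,
                 discard_frac: float = DEFAULT_DISCARD_FRAC) -> pd.DataFrame:
    """Convenience wrapper: distance profile for one gear of a monthly grid."""
    from .local_metrics import local_relative_sd

    layer = effort.sel(gear=gear)
    sd = local_relative_sd(layer.expand_dims("gear")).isel(gear=0)
    mean = layer.mean(dim="month")
    out = binned_variability(sd, mean, distances,
                             bin_width_km=bin_width_km,
                             discard_frac=discard_frac)
    out.insert(0, "gear", gear)
    return out
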