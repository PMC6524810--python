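"""Per-cell seasonal statistics on monthly effort grids.

Three indicators describe the local seasonal cycle:

* the seasonality index ``SI = (1/ē_a) Σ_n |e_n − ē_a/12|`` over the 12
  climatological months, ranging from 0 (even effort year-round) to
  22/12 ≈ 1.83 (all effort in a single month);
* the local relative standard deviation ``sd(e/ē)`` of the monthly
  series around its full-window mean;
* the peak month of the climatological first principal component of the
  year-by-month effort matrix, reported only where a clear seasonal
  cycle is identified (effort in every year, and the first component
  explaining at least two thirds of the variance).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grids import GridSpec
from .ingest import months_period_index

logger = logging.getLogger(__name__)

SI_MAX = 22.0 / 12.0
VARIANCE_THRESHOLD = 2.0 / 3.0
DOMINANT_GEAR_THRESHOLD = 0.75

#: peak-month quality codes
QC_OK = 0
QC_ZERO_YEAR = 1
QC_LOW_VARIANCE = 2


def _check_whole_years(months: pd.PeriodIndex) -> list[int]:
    by_year: dict[int, set] = {}
    for p in months:
        by_year.setdefault(p.year, set()).add(p.month)
    bad = [y for y, ms in by_year.items() if ms != set(range(1, 13))]
    if bad:
        raise ValueError(f"incomplete calendar years in grid: {bad}")
    return sorted(by_year)


def climatology(effort: xr.DataArray) -> xr.DataArray:
    """Climatological monthly effort ``e_n``: per gear and cell, the mean
    across years of each calendar month's daily-mean effort.

    Requires whole calendar years.  Result dims:
    ``(gear, clim_month, lat, lon)`` with ``clim_month`` 1..12.
    """
    months = months_period_index(effort)
    _check_whole_years(months)
    da = effort.assign_coords(clim_month=("month", months.month))
    clim = da.groupby("clim_month").mean(dim="month")
    clim = clim.transpose("gear", "clim_month", "lat", "lon")
    clim.name = "climatological_effort"
    clim.attrs.update(effort.attrs)
    return clim


def annual_total(clim: xr.DataArray) -> xr.DataArray:
    """``ē_a``: sum of the 12 climatological monthly values."""
    return clim.sum(dim="clim_month")


def seasonality_index(clim: xr.DataArray, per_gear: bool = False) -> xr.DataArray:
    """Seasonality index SI per cell.

    ``SI = (1/ē_a) Σ_{n=1..12} |e_n − ē_a/12|`` on the climatological
    months; 0 for an even annual distribution, 22/12 when all effort
    falls in one month.  Cells with ``ē_a = 0`` are NaN (flagged
    invalid).  By default computed on all-gear summed effort; with
    ``per_gear=True`` one SI layer per gear.
    """
    if not per_gear and "gear" in clim.dims:
        clim = clim.sum(dim="gear")
    ea = clim.sum(dim="clim_month")
    dev = np.abs(clim - ea / 12.0).sum(dim="clim_month")
    si = xr.where(ea > 0, dev / ea, np.nan)
    si.name = "SI"
    return si


def local_relative_sd(effort: xr.DataArray, per_gear: bool = True) -> xr.DataArray:
    """Sample sd of ``e(i,j)/ē(i,j)`` over the monthly series.

    ``ē`` is the mean over all months in the window.  NaN where the mean
    is zero.  Scale-invariant: multiplying a cell's series by a positive
    constant leaves the value unchanged.
    """
    if not per_gear and "gear" in effort.dims:
        effort = effort.sum(dim="gear")
    mean = effort.mean(dim="month")
    # sd(e/ē) = sd(e)/ē; avoids forming all-NaN relative slices
    sd = effort.std(dim="month", ddof=1) / xr.where(mean > 0, mean, np.nan)
    sd.name = "local_relative_sd"
    return sd


def _year_month_matrix(effort: xr.DataArray) -> tuple[np.ndarray, list[int]]:
    """All-gear effort reshaped to (lat, lon, year, month 1..12)."""
    months = months_period_index(effort)
    years = _check_whole_years(months)
    total = effort.sum(dim="gear") if "gear" in effort.dims else effort
    total = total.transpose("month", "lat", "lon")
    nlat, nlon = total.sizes["lat"], total.sizes["lon"]
    mat = np.empty((nlat, nlon, len(years), 12), dtype=float)
    vals = total.values
    for k, p in enumerate(months):
        yi = years.index(p.year)
        mat[:, :, yi, p.month - 1] = vals[k]
    return mat, years


def peak_month(effort: xr.DataArray,
               variance_threshold: float = VARIANCE_THRESHOLD) -> xr.Dataset:
    """Peak month of the climatological first principal component.

    Per cell, on all-gear summed effort: the year-by-month matrix is
    centered by its grand mean and decomposed by SVD; the explained
    variance fraction of the first component is ``σ₁²/Σσ_k²``.  Cells
    failing either filter — (1) nonzero annual effort in every year,
    (2) explained variance below ``variance_threshold`` — carry no peak.
    The first right-singular 12-vector, sign-aligned to correlate
    positively with the cell's mean monthly profile, gives the seasonal
    component; the peak month is its argmax (ties to the earliest
    month).

    Returns a Dataset with ``peak_month`` (NaN where undefined),
    ``explained_variance`` and integer ``qc`` (0 ok, 1 failed zero-year
    filter, 2 failed variance filter).
    """
    mat, years = _year_month_matrix(effort)
    nlat, nlon, ny, _ = mat.shape
    flat = mat.reshape(-1, ny, 12)

    annual = flat.sum(axis=2)                      # (ncell, ny)
    pass_years = (annual > 0).all(axis=1)

    centered = flat - flat.mean(axis=(1, 2), keepdims=True)
    # batched SVD of the ny x 12 matrices
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    power = (s**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ev = np.where(power > 0, s[:, 0] ** 2 / np.where(power > 0, power, 1.0), 0.0)
    v1 = vt[:, 0, :]                               # (ncell, 12)

    # sign: positive correlation with the mean monthly profile
    profile = flat.mean(axis=1)
    profile_c = profile - profile.mean(axis=1, keepdims=True)
    corr = (v1 * profile_c).sum(axis=1)
    v1 = np.where(corr[:, None] < 0, -v1, v1)

    peak = np.argmax(v1, axis=1) + 1.0

    qc = np.full(flat.shape[0], QC_OK, dtype=np.int8)
    pass_var = ev >= variance_threshold
    qc[~pass_var] = QC_LOW_VARIANCE
    qc[~pass_years] = QC_ZERO_YEAR
    ok = pass_years & pass_var
    peak = np.where(ok, peak, np.nan)

    coords = {"lat": effort["lat"], "lon": effort["lon"]}
    return xr.Dataset(
        {
            "peak_month": (("lat", "lon"), peak.reshape(nlat, nlon)),
            "explained_variance": (("lat", "lon"), ev.reshape(nlat, nlon)),
            "qc": (("lat", "lon"), qc.reshape(nlat, nlon)),
        },
        coords=coords,
        attrs={
            "variance_threshold": variance_threshold,
            "years": years,
            "qc_legend": "0 ok; 1 zero-effort year; 2 low explained variance",
        },
    )


def dominant_gear(effort: xr.DataArray,
                  threshold: float = DOMINANT_GEAR_THRESHOLD
                  ) -> tuple[xr.DataArray, dict]:
    """Per-cell dominant gear: the gear holding strictly more than
    ``threshold`` of the cell's window-summed effort, else none.

    Returns an integer-coded map (-1 = none) and the code legend.
    """
    totals = (effort * effort["days_in_month"]).sum(dim="month")
    grand = totals.sum(dim="gear")
    frac = totals / xr.where(grand > 0, grand, np.nan)
    gears = [str(g) for g in effort["gear"].values]
    best = frac.fillna(0.0).argmax(dim="gear")
    best_frac = frac.fillna(0.0).max(dim="gear")
    code = xr.where((best_frac > threshold) & (grand > 0), best, -1)
    code.name = "dominant_gear"
    legend = {int(i): g for i, g in enumerate(gears)}
    legend[-1] = "none"
    return code.astype(np.int16), legend


# ---------------------------------------------------------------------------
# resolution sensitivity harness
# ---------------------------------------------------------------------------

def resolution_harness(records: pd.DataFrame,
                       resolutions=(0.5, 1.0, 4.0),
                       vessels: pd.DataFrame | None = None) -> dict:
    """Recompute SI and peak-month maps at several grid resolutions.

    Rasterizes the same record stream independently at each resolution
    (vessel-cell-day dedup applied per resolution) and reports, for each
    fine/coarse pair, the Spearman rank correlation between (a) SI from
    the fine-grid effort block-aggregated into coarse cells and (b) SI
    from native coarse rasterization.

    Returns ``{"maps": {res: {"SI": ..., "peak": ...}},
    "rank_correlation": {(fine, coarse): rho}}``.
    """
    from .ingest import monthly_aggregate, rasterize_daily

    resolutions = sorted(float(r) for r in resolutions)
    maps: dict[float, dict] = {}
    efforts: dict[float, xr.DataArray] = {}
    for res in resolutions:
        grid = GridSpec(res)
        daily = rasterize_daily(records, grid, vessels=vessels)
        eff = monthly_aggregate(daily, grid)
        efforts[res] = eff
        clim = climatology(eff)
        maps[res] = {"SI": seasonality_index(clim), "peak": peak_month(eff)}

    corr: dict[tuple[float, float], float] = {}
    for a in resolutions:
        for b in resolutions:
            if b <= a:
                continue
            GridSpec(a).coarsen_factor(GridSpec(b))  # validates nesting
            agg = _block_aggregate(efforts[a], GridSpec(b))
            si_agg = seasonality_index(climatology(agg))
            si_native = maps[b]["SI"]
            si_agg, si_native = xr.align(si_agg, si_native, join="inner")
            x = si_agg.values.ravel()
            y = si_native.values.ravel()
            valid = np.isfinite(x) & np.isfinite(y)
            if valid.sum() >= 3:
                rho = float(stats.spearmanr(x[valid], y[valid]).statistic)
            else:
                rho = float("nan")
            corr[(a, b)] = rho
    return {"maps": maps, "rank_correlation": corr}


def _block_aggregate(effort: xr.DataArray, coarse: GridSpec) -> xr.DataArray:
    """Sum fine-grid effort into the enclosing coarse cells."""
    lons = effort["lon"].values
    lats = effort["lat"].values
    col, _ = coarse.cell_index(lons, np.zeros_like(lons))
    _, row = coarse.cell_index(np.zeros_like(lats), lats)
    cols = np.unique(col)
    rows = np.unique(row)
    ci = np.searchsorted(cols, col)
    ri = np.searchsorted(rows, row)
    eff = effort.transpose("gear", "month", "lat", "lon")
    shape = (eff.sizes["gear"], eff.sizes["month"], len(rows), len(cols))
    vals = np.zeros(shape)
    np.add.at(vals, (slice(None), slice(None), ri[:, None], ci[None, :]),
              eff.values)
    lon_c, _ = coarse.cell_center(cols, np.zeros_like(cols))
    _, lat_c = coarse.cell_center(np.zeros_like(rows), rows)
    out = xr.DataArray(
        vals, dims=("gear", "month", "lat", "lon"),
        coords={"gear": eff["gear"], "month": eff["month"],
                "lat": lat_c, "lon": lon_c,
                "days_in_month": ("month", eff["days_in_month"].values)},
        name="effort_per_day")
    out.attrs.update(effort.attrs)
    out.attrs["resolution_deg"] = coarse.resolution_deg
    return out
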