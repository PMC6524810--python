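"""Ingestion of daily per-vessel fishing records into gridded vessel-day effort.

The atomic effort unit is the vessel-day: one vessel observed fishing at
least once in one grid cell on one calendar day.  Monthly effort
``e_g(i,j)`` is the monthly vessel-day sum in a cell divided by the
number of days in that month (fishing-vessel-days per day).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import shapely
from shapely.geometry import shape as shapely_shape

from .grids import GridSpec, KM_PER_NM

logger = logging.getLogger(__name__)

#: The six base gear classes; purse seiners may be refined into the two
#: purse sub-classes by :func:`split_purse_seiners`.
GEAR_CLASSES = (
    "trawlers",
    "fixed_gear",
    "drifting_longlines",
    "purse_seines",
    "squid_jigger",
    "other",
)

PURSE_SUBCLASSES = ("purse_coastal", "purse_high_seas")

#: Purse-seine split thresholds: hull length and mean fishing distance
#: from shore.
PURSE_LENGTH_M = 40.0
PURSE_SHORE_NM = 50.0

DEFAULT_YEARS = (2015, 2016, 2017)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _as_frame(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


def read_vessel_table(path) -> pd.DataFrame:
    """Read the vessel metadata table.

    Expects columns ``vessel_id, gear_class, length_m`` and optionally
    ``mean_shore_distance_nm``.  Unknown gear strings are mapped to
    ``"other"`` with a warning; missing mandatory columns or an empty
    table are hard errors.
    """
    df = _as_frame(path)
    if df.empty:
        raise ValueError(f"vessel table {path!r} is empty")
    for col in ("vessel_id", "gear_class", "length_m"):
        if col not in df.columns:
            raise ValueError(f"vessel table missing mandatory column {col!r}")
    df["vessel_id"] = df["vessel_id"].astype(str)
    df["gear_class"] = df["gear_class"].astype(str).str.strip()
    known = set(GEAR_CLASSES) | set(PURSE_SUBCLASSES)
    unknown = ~df["gear_class"].isin(known)
    if unknown.any():
        bad = sorted(df.loc[unknown, "gear_class"].unique())
        logger.warning("unknown gear classes %s mapped to 'other'", bad)
        df.loc[unknown, "gear_class"] = "other"
    df["length_m"] = pd.to_numeric(df["length_m"], errors="coerce")
    if (df["length_m"] < 0).any():
        raise ValueError("negative vessel length in table")
    if "mean_shore_distance_nm" in df.columns:
        df["mean_shore_distance_nm"] = pd.to_numeric(
            df["mean_shore_distance_nm"], errors="coerce"
        )
    else:
        df["mean_shore_distance_nm"] = np.nan
    return df.reset_index(drop=True)


def read_fishing_records(path, max_reject_frac: float = 0.5) -> pd.DataFrame:
    """Read daily fishing records ``vessel_id,date,lat,lon,is_fishing``.

    Records flagged not-fishing are dropped silently.  Records with an
    unparseable date or out-of-range coordinates are rejected and
    counted; more than ``max_reject_frac`` rejects is a hard error.
    Longitude 180 wraps to -180.  The number of rejects is stored in
    ``df.attrs["n_rejected"]``.
    """
    df = _as_frame(path)
    for col in ("vessel_id", "date", "lat", "lon", "is_fishing"):
        if col not in df.columns:
            raise ValueError(f"fishing records missing column {col!r}")
    n_input = len(df)
    df["vessel_id"] = df["vessel_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    bad = (
        df["date"].isna()
        | df["lat"].isna()
        | df["lon"].isna()
        | (df["lat"] < -90.0)
        | (df["lat"] > 90.0)
        | (df["lon"] < -180.0)
        | (df["lon"] > 180.0)
    )
    n_rejected = int(bad.sum())
    if n_input and n_rejected / n_input > max_reject_frac:
        raise ValueError(
            f"{n_rejected}/{n_input} records rejected (> {max_reject_frac:.0%})"
        )
    if n_rejected:
        logger.warning("rejected %d malformed records", n_rejected)
    df = df.loc[~bad].copy()
    df.loc[df["lon"] == 180.0, "lon"] = -180.0
    fishing = pd.to_numeric(df["is_fishing"], errors="coerce").fillna(0) != 0
    df = df.loc[fishing, ["vessel_id", "date", "lat", "lon"]].reset_index(drop=True)
    df.attrs["n_rejected"] = n_rejected
    df.attrs["n_input"] = n_input
    return df


# ---------------------------------------------------------------------------
# vessel filters
# ---------------------------------------------------------------------------

def filter_continuous_vessels(records: pd.DataFrame,
                              years=DEFAULT_YEARS) -> tuple[pd.DataFrame, dict]:
    """Keep only vessels with >= 1 fishing record in every listed year.

    This implements the continuity filter used to remove the trend from
    gradual AIS adoption: a vessel must be active in each calendar year
    of the window.  Returns the filtered records and a summary dict with
    kept/dropped vessel counts.
    """
    years = set(int(y) for y in years)
    yr = records["date"].dt.year
    years_by_vessel = records.assign(year=yr).groupby("vessel_id")["year"].agg(set)
    keep_ids = set(years_by_vessel.index[years_by_vessel.apply(lambda s: years <= s)])
    kept = records[records["vessel_id"].isin(keep_ids)].reset_index(drop=True)
    summary = {
        "n_vessels_in": int(len(years_by_vessel)),
        "n_vessels_kept": int(len(keep_ids)),
        "n_vessels_dropped": int(len(years_by_vessel) - len(keep_ids)),
        "n_records_kept": int(len(kept)),
    }
    if not keep_ids:
        logger.warning("continuity filter kept no vessels for years %s", sorted(years))
    return kept, summary


def mean_shore_distance_nm(records: pd.DataFrame, shore_raster) -> pd.Series:
    """Per-vessel mean distance from shore of fishing positions, in nm.

    ``shore_raster`` is a (lat, lon) DataArray of distance-to-shore in
    km; positions are interpolated bilinearly.
    """
    from .port_access import interpolate_raster

    d_km = interpolate_raster(shore_raster,
                              records["lon"].to_numpy(),
                              records["lat"].to_numpy())
    s = pd.Series(d_km / KM_PER_NM, index=records["vessel_id"].to_numpy())
    return s.groupby(level=0).mean()


def split_purse_seiners(vessels: pd.DataFrame,
                        records: pd.DataFrame | None = None,
                        shore_raster=None) -> pd.DataFrame:
    """Refine ``purse_seines`` into coastal vs high-seas sub-classes.

    High-seas purse seiners are vessels longer than 40 m whose mean
    fishing position lies more than 50 nm from shore; every other purse
    seiner is coastal.  Mean shore distance is taken from the vessel
    table when present, otherwise computed from the vessel's fishing
    positions against ``shore_raster``.  A purse seiner with unknown
    length is classified coastal with a warning.
    """
    vessels = vessels.copy()
    purse = vessels["gear_class"] == "purse_seines"
    if not purse.any():
        return vessels
    dist = vessels["mean_shore_distance_nm"].copy()
    need = purse & dist.isna()
    if need.any():
        if records is None or shore_raster is None:
            raise ValueError(
                "purse seiners lack mean_shore_distance_nm and no records/"
                "shore raster supplied to derive it"
            )
        derived = mean_shore_distance_nm(
            records[records["vessel_id"].isin(vessels.loc[need, "vessel_id"])],
            shore_raster,
        )
        dist.loc[need] = vessels.loc[need, "vessel_id"].map(derived).to_numpy()
    length = vessels["length_m"]
    missing_len = purse & length.isna()
    if missing_len.any():
        logger.warning(
            "%d purse seiners lack a length; classified coastal",
            int(missing_len.sum()),
        )
    high = purse & (length > PURSE_LENGTH_M) & (dist > PURSE_SHORE_NM)
    vessels.loc[purse, "gear_class"] = "purse_coastal"
    vessels.loc[high, "gear_class"] = "purse_high_seas"
    vessels["mean_shore_distance_nm"] = dist
    return vessels


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_daily(records: pd.DataFrame, grid: GridSpec,
                    vessels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Daily vessel-day counts per (gear, date, cell).

    A vessel contributes at most one vessel-day per cell per date,
    however many positions it reports there; a vessel fishing in k
    distinct cells on one date contributes one vessel-day in each.
    Returns a long-format frame ``gear, date, col, row, count``.
    """
    df = records.copy()
    if "gear_class" not in df.columns:
        if vessels is None:
            raise ValueError("records lack gear_class and no vessel table given")
        gear_map = vessels.set_index("vessel_id")["gear_class"]
        df["gear_class"] = df["vessel_id"].map(gear_map)
        df = df.dropna(subset=["gear_class"])
    col, row = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["col"] = col
    df["row"] = row
    df["date"] = df["date"].dt.normalize()
    dedup = df.drop_duplicates(subset=["vessel_id", "date", "col", "row"])
    counts = (
        dedup.groupby(["gear_class", "date", "col", "row"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"gear_class": "gear"})
    )
    return counts


def _full_months(dates: pd.Series) -> pd.PeriodIndex:
    """Months fully covered by [min(dates), max(dates)]."""
    lo, hi = dates.min(), dates.max()
    months = pd.period_range(lo, hi, freq="M")
    # a month is covered when its first and last day are inside the window
    keep = [m for m in months
            if lo.normalize() <= m.start_time and m.end_time.normalize() <= hi.normalize()]
    return pd.PeriodIndex(keep, freq="M")


def monthly_aggregate(daily: pd.DataFrame, grid: GridSpec,
                      months: pd.PeriodIndex | None = None,
                      extent: str = "data") -> xr.DataArray:
    """Aggregate daily vessel-day counts to monthly effort per day.

    ``e_g(i,j)`` for a month is the monthly vessel-day sum divided by the
    number of days in that month (29 for a leap February).  Months not
    fully covered by the record window are excluded with a warning.

    Returns a DataArray with dims ``(gear, month, lat, lon)`` in
    fishing-vessel-days per day; coordinate ``days_in_month`` rides on
    ``month``.  ``extent='data'`` restricts lat/lon to the bounding box
    of occupied cells; ``extent='global'`` keeps the full grid.
    """
    if daily.empty:
        raise ValueError("no daily counts to aggregate")
    dates = pd.to_datetime(daily["date"])
    if months is None:
        months = _full_months(dates)
        all_months = pd.period_range(dates.min(), dates.max(), freq="M")
        if len(months) < len(all_months):
            logger.warning(
                "excluding %d partially covered month(s)",
                len(all_months) - len(months),
            )
    if len(months) == 0:
        raise ValueError("no fully covered months in the record window")

    df = daily.copy()
    df["month"] = dates.dt.to_period("M")
    df = df[df["month"].isin(set(months))]

    gears = sorted(df["gear"].unique())
    if extent == "global":
        cols = np.arange(grid.n_lon)
        rows = np.arange(grid.n_lat)
    else:
        cols = np.arange(df["col"].min(), df["col"].max() + 1)
        rows = np.arange(df["row"].min(), df["row"].max() + 1)

    shape = (len(gears), len(months), len(rows), len(cols))
    values = np.zeros(shape, dtype=float)
    gear_idx = {g: k for k, g in enumerate(gears)}
    month_idx = {m: k for k, m in enumerate(months)}
    gi = df["gear"].map(gear_idx).to_numpy()
    mi = df["month"].map(month_idx).to_numpy()
    ri = df["row"].to_numpy() - rows[0]
    ci = df["col"].to_numpy() - cols[0]
    np.add.at(values, (gi, mi, ri, ci), df["count"].to_numpy().astype(float))

    days = np.array([m.days_in_month for m in months], dtype=float)
    values /= days[None, :, None, None]

    lon, _ = grid.cell_center(cols, np.zeros_like(cols))
    _, lat = grid.cell_center(np.zeros_like(rows), rows)
    da = xr.DataArray(
        values,
        dims=("gear", "month", "lat", "lon"),
        coords={
            "gear": gears,
            "month": [m.to_timestamp() for m in months],
            "lat": lat,
            "lon": lon,
            "days_in_month": ("month", days),
        },
        name="effort_per_day",
        attrs={
            "units": "fishing-vessel-days per day",
            "resolution_deg": grid.resolution_deg,
        },
    )
    return da


def total_vessel_days(effort: xr.DataArray) -> float:
    """Total vessel-days represented by a monthly effort grid."""
    return float((effort * effort["days_in_month"]).sum())


def months_period_index(effort: xr.DataArray) -> pd.PeriodIndex:
    return pd.DatetimeIndex(effort["month"].values).to_period("M")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

@dataclass
class CellMask:
    """A set of grid cells, e.g. an EEZ footprint, on a given grid."""

    grid: GridSpec
    cells: frozenset = field(default_factory=frozenset)  # of (col, row)
    label: str = ""

    def __post_init__(self) -> None:
        for c, r in self.cells:
            if not (0 <= c < self.grid.n_lon and 0 <= r < self.grid.n_lat):
                raise ValueError(f"cell {(c, r)} outside grid")

    @classmethod
    def from_polygon(cls, grid: GridSpec, polygon, label: str = "") -> "CellMask":
        """Cells whose centers fall inside the (multi)polygon."""
        lon_c = grid.lon_centers
        lat_c = grid.lat_centers
        lon2, lat2 = np.meshgrid(lon_c, lat_c)
        inside = shapely.contains_xy(polygon, lon2.ravel(), lat2.ravel())
        rows, cols = np.divmod(np.flatnonzero(inside), len(lon_c))
        cells = frozenset(zip(cols.tolist(), rows.tolist()))
        if not cells:
            logger.warning("polygon mask %r contains no cell centers", label)
        return cls(grid=grid, cells=cells, label=label)

    @classmethod
    def from_geojson(cls, path, grid: GridSpec, label: str = "") -> "CellMask":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geom = shapely_shape(gj["features"][0]["geometry"])
        elif gj.get("type") == "Feature":
            geom = shapely_shape(gj["geometry"])
        else:
            geom = shapely_shape(gj)
        return cls.from_polygon(grid, geom, label=label or str(path))

    @classmethod
    def from_cell_centers_csv(cls, path, grid: GridSpec, label: str = "") -> "CellMask":
        df = pd.read_csv(path)
        col, row = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
        return cls(grid=grid,
                   cells=frozenset(zip(col.tolist(), row.tolist())),
                   label=label or str(path))

    def boolean(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Boolean (lat, lon) membership array on the given coordinate axes."""
        col, _ = self.grid.cell_index(lon, np.zeros_like(lon))
        _, row = self.grid.cell_index(np.zeros_like(lat), lat)
        member = np.zeros((len(lat), len(lon)), dtype=bool)
        cellset = self.cells
        for i, r in enumerate(row):
            for j, c in enumerate(col):
                if (int(c), int(r)) in cellset:
                    member[i, j] = True
        return member


def apply_mask(effort: xr.DataArray, mask: CellMask,
               mode: str = "remove") -> xr.DataArray:
    """Zero out cells inside (``remove``) or outside (``keep``) the mask.

    The two modes partition the grid: remove-mode plus keep-mode output
    equals the input cellwise.
    """
    if mode not in ("remove", "keep"):
        raise ValueError(f"mode must be 'remove' or 'keep', got {mode!r}")
    if abs(mask.grid.resolution_deg - effort.attrs.get(
            "resolution_deg", mask.grid.resolution_deg)) > 1e-9:
        raise ValueError("mask grid resolution does not match effort grid")
    member = mask.boolean(effort["lat"].values, effort["lon"].values)
    keep = ~member if mode == "remove" else member
    out = effort.where(xr.DataArray(keep, dims=("lat", "lon"),
                                    coords={"lat": effort["lat"],
                                            "lon": effort["lon"]}), 0.0)
    out.attrs.update(effort.attrs)
    out.attrs["mask_label"] = mask.label
    out.attrs["mask_mode"] = mode
    return out


# ---------------------------------------------------------------------------
# gridded output
# ---------------------------------------------------------------------------

def effort_to_netcdf(effort: xr.DataArray, path) -> None:
    """Write a monthly effort grid to netCDF3 (one variable per gear)."""
    ds = xr.Dataset(
        {f"effort_{g}": effort.sel(gear=g).drop_vars("gear")
         for g in effort["gear"].values},
        attrs=effort.attrs,
    )
    ds.to_netcdf(path, engine="scipy")


def effort_from_netcdf(path) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    gears = [v.removeprefix("effort_") for v in ds.data_vars]
    da = xr.concat([ds[f"effort_{g}"] for g in gears], dim="gear")
    da = da.assign_coords(gear=gears).transpose("gear", "month", "lat", "lon")
    da.name = "effort_per_day"
    da.attrs.update(ds.attrs)
    return da


def effort_to_csv(effort: xr.DataArray, path) -> None:
    """Long-format fallback: gear,year,month,lon,lat,effort_per_day."""
    df = effort.to_dataframe().reset_index()
    df = df[df["effort_per_day"] > 0]
    ts = pd.DatetimeIndex(df["month"])
    out = pd.DataFrame({
        "gear": df["gear"],
        "year": ts.year,
        "month": ts.month,
        "lon": df["lon"],
        "lat": df["lat"],
        "effort_per_day": df["effort_per_day"],
    })
    out.to_csv(path, index=False)
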