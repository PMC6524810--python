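"""Synthetic AIS-like fishing-effort generator with known ground truth.

Two generating modes stand in for satellite-observed effort data:

* **parametric** — per-gear spatial base fields (coastal bands decaying
  away from a synthetic coastline, or basin-wide), a cosine seasonal
  cycle per cell with a controlled peak month and amplitude, uniform
  boreal-winter holiday deficits of a stated whole-day magnitude, a
  summer moratorium confined to one masked region, and Poisson (or
  deterministic) sampling of integer vessel-days assigned to a vessel
  pool that survives the continuity filter;
* **bioeconomic** — effort evolving under a profit-and-regulation
  dynamic dE/dt = κ_e(pqB − c)E − R with harvest H = qEB, integrated
  by a daily Euler step and thinned into vessel-day records.

Every injected parameter is stored in a truth record so downstream
estimates can be checked against construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import Polygon, mapping

from .grids import EARTH_RADIUS_KM, KM_PER_NM, GridSpec, haversine_km
from .ingest import CellMask

logger = logging.getLogger(__name__)

#: mean month length used to convert monthly-rate units to daily rates
DAYS_PER_MONTH = 365.25 / 12.0


# ---------------------------------------------------------------------------
# scenario definition
# ---------------------------------------------------------------------------

@dataclass
class GearSpec:
    """One synthetic gear: spatial habit, seasonal cycle, fleet."""

    name: str
    share_pct: float
    habitat: str = "coastal"            # "coastal" | "basin"
    coastal_band_km: float = 300.0
    amplitude: float = 0.3              # seasonal amplitude in [0, 1]
    #: when set, the amplitude ramps linearly with distance to the
    #: nearest synthetic port, reaching ``amplitude`` at this distance
    amplitude_ramp_km: float | None = None
    n_vessels: int = 60
    length_range: tuple = (20.0, 40.0)
    n_dropout_vessels: int = 0          # vessels active in only one year

    def __post_init__(self):
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude}")
        if self.habitat not in ("coastal", "basin"):
            raise ValueError(f"unknown habitat {self.habitat!r}")


@dataclass
class Moratorium:
    """Seasonal closure confined to a polygonal region."""

    region: list = field(default_factory=list)      # [(lon, lat), ...] ring
    windows: list = field(default_factory=list)     # [(start, end)] ISO dates
    factor: float = 0.1                             # effort multiplier inside

    def polygon(self) -> Polygon:
        poly = Polygon(self.region)
        if poly.is_empty or not poly.is_valid or poly.area == 0:
            raise ValueError("degenerate moratorium polygon")
        return poly


def _default_gears() -> list:
    # Effort shares follow the observed global composition (trawling
    # about half, then fixed gears, longlines, purse seiners, jiggers);
    # the 11% purse share is split 7% coastal / 4% high-seas.  Coastal
    # gears hug the shelf; pelagic gears spread basin-wide with stronger
    # seasonal cycles.
    return [
        GearSpec("trawlers", 53.0, "coastal", 300.0, 0.2, None, 180, (25.0, 60.0)),
        GearSpec("fixed_gear", 15.0, "coastal", 200.0, 0.2, None, 80, (15.0, 35.0)),
        GearSpec("drifting_longlines", 13.0, "basin", 300.0, 0.6, None, 70, (25.0, 55.0)),
        GearSpec("purse_coastal", 7.0, "coastal", 150.0, 0.7, None, 50, (20.0, 39.0)),
        GearSpec("purse_high_seas", 4.0, "basin", 300.0, 0.6, None, 30, (45.0, 80.0)),
        GearSpec("squid_jigger", 4.0, "basin", 300.0, 0.8, None, 30, (30.0, 55.0)),
        GearSpec("other", 4.0, "coastal", 300.0, 0.3, None, 30, (10.0, 30.0)),
    ]


def _default_moratorium() -> Moratorium:
    # A summer closure in the north-west corner of the domain, with the
    # observed closure calendar: mid-May to mid-September in the first
    # two years, starting two weeks earlier in the third.  The region
    # spans 12 deg of latitude so that removing it keeps the cyclic
    # peak-month field balanced (every phase equally represented).
    return Moratorium(
        region=[(100.0, 24.0), (120.0, 24.0), (120.0, 36.0), (100.0, 36.0)],
        windows=[("2015-05-16", "2015-09-16"),
                 ("2016-05-16", "2016-09-16"),
                 ("2017-05-01", "2017-09-16")],
        factor=0.1,
    )


@dataclass
class Scenario:
    """Full parameterization of the parametric generator."""

    resolution_deg: float = 1.0
    lon_min: float = 100.0
    lon_max: float = 160.0
    lat_min: float = -24.0
    lat_max: float = 36.0
    years: tuple = (2015, 2016, 2017)
    mean_total_effort: float = 600.0    # vessel-days per day, domain total
    gears: list = field(default_factory=_default_gears)
    #: "cyclic" assigns peak months cyclically along latitude rows (all
    #: twelve phases equally represented within each longitude column,
    #: so the seasonal term cancels in the global sum); "latitude" maps
    #: latitude onto the calendar; an int fixes one peak month.
    peak_field: object = "cyclic"
    holidays: dict = field(default_factory=lambda: {12: 4.0, 1: 4.0, 2: 2.5})
    moratorium: Moratorium | None = field(default_factory=_default_moratorium)
    ports: list = field(default_factory=lambda: [(100.0, 6.0)])
    coast_lon: float | None = 100.0     # meridian coastline; None = no coast
    noise: str = "poisson"              # "poisson" | "none"
    seed: int = 0

    def __post_init__(self):
        total = sum(g.share_pct for g in self.gears)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"gear shares sum to {total}, expected 100")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise mode {self.noise!r}")
        span_lon = self.lon_max - self.lon_min
        span_lat = self.lat_max - self.lat_min
        if span_lon <= 0 or span_lat <= 0:
            raise ValueError("empty domain")

    # -- geometry ---------------------------------------------------------
    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.resolution_deg)

    def domain_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon_centers, lat_centers) of the domain's cells."""
        g = self.grid
        lon = g.lon_centers
        lat = g.lat_centers
        lon = lon[(lon > self.lon_min) & (lon < self.lon_max)]
        lat = lat[(lat > self.lat_min) & (lat < self.lat_max)]
        return lon, lat

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(f"{min(self.years)}-01-01",
                             f"{max(self.years)}-12-31", freq="D")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if "gears" in d:
            d["gears"] = [GearSpec(**{**g, "length_range": tuple(g["length_range"])})
                          if isinstance(g, dict) else g for g in d["gears"]]
        if d.get("moratorium") is not None and isinstance(d["moratorium"], dict):
            m = d["moratorium"]
            d["moratorium"] = Moratorium(
                region=[tuple(p) for p in m["region"]],
                windows=[tuple(w) for w in m["windows"]],
                factor=m.get("factor", 0.1),
            )
        if "years" in d:
            d["years"] = tuple(d["years"])
        if "ports" in d:
            d["ports"] = [tuple(p) for p in d["ports"]]
        if "holidays" in d:
            d["holidays"] = {int(k): float(v) for k, v in d["holidays"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# expected-intensity machinery (the analytic truth)
# ---------------------------------------------------------------------------

def _shore_distance_km(scenario: Scenario, lon2, lat2) -> np.ndarray:
    if scenario.coast_lon is None:
        return np.full(np.shape(lon2), np.inf)
    return haversine_km(scenario.coast_lon, lat2, lon2, lat2)


def _port_distance_km(scenario: Scenario, lon2, lat2) -> np.ndarray:
    if not scenario.ports:
        raise ValueError("scenario specifies no ports")
    stack = [haversine_km(p[0], p[1], lon2, lat2) for p in scenario.ports]
    return np.min(np.stack(stack), axis=0)


def _peak_month_field(scenario: Scenario, nlat: int, nlon: int,
                      lat: np.ndarray) -> np.ndarray:
    pf = scenario.peak_field
    if isinstance(pf, (int, np.integer)):
        return np.full((nlat, nlon), int(pf))
    if pf == "cyclic":
        rows = (np.arange(nlat) % 12) + 1
        return np.tile(rows[:, None], (1, nlon))
    if pf == "latitude":
        frac = (lat - lat.min()) / max(lat.max() - lat.min(), 1e-12)
        rows = (np.round(frac * 11) + 1).astype(int)  # south 1 .. north 12
        return np.tile(rows[:, None], (1, nlon))
    raise ValueError(f"unknown peak_field {pf!r}")


def _base_field(gear: GearSpec, scenario: Scenario,
                d_shore: np.ndarray) -> np.ndarray:
    if gear.habitat == "coastal" and np.isfinite(d_shore).any():
        raw = np.exp(-d_shore / gear.coastal_band_km)
    else:
        raw = np.ones_like(d_shore)
    raw = np.where(np.isfinite(raw), raw, 1.0)
    target = gear.share_pct / 100.0 * scenario.mean_total_effort
    return raw / raw.sum() * target


def _amplitude_field(gear: GearSpec, d_port: np.ndarray) -> np.ndarray:
    if gear.amplitude_ramp_km is None:
        return np.full_like(d_port, gear.amplitude, dtype=float)
    ramp = np.clip(d_port / gear.amplitude_ramp_km, 0.0, 1.0)
    return gear.amplitude * ramp


def _holiday_factor(scenario: Scenario, dates: pd.DatetimeIndex) -> np.ndarray:
    """Daily multiplier implementing the whole-day holiday deficits."""
    fac = np.ones(len(dates))
    dim = dates.days_in_month.to_numpy()
    for m, h in scenario.holidays.items():
        sel = dates.month == int(m)
        fac[sel] = 1.0 - float(h) / dim[sel]
    return fac


def _moratorium_daily(scenario: Scenario, dates: pd.DatetimeIndex,
                      member: np.ndarray) -> np.ndarray:
    """(n_days, n_cells) multiplier; 1 outside windows/region."""
    n_days, n_cells = len(dates), member.size
    fac = np.ones((n_days, n_cells))
    if scenario.moratorium is None:
        return fac
    in_window = np.zeros(n_days, dtype=bool)
    for start, end in scenario.moratorium.windows:
        in_window |= (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    fac[np.ix_(in_window, member.ravel())] = scenario.moratorium.factor
    return fac


class ScenarioFields:
    """Deterministic per-cell fields and daily intensities of a scenario."""

    def __init__(self, scenario: Scenario):
        self.scenario = scenario
        self.lon, self.lat = scenario.domain_cells()
        self.lon2, self.lat2 = np.meshgrid(self.lon, self.lat)
        self.nlat, self.nlon = self.lon2.shape
        self.d_shore = _shore_distance_km(scenario, self.lon2, self.lat2)
        self.d_port = _port_distance_km(scenario, self.lon2, self.lat2)
        self.peak = _peak_month_field(scenario, self.nlat, self.nlon, self.lat)
        self.dates = scenario.dates()
        self.holiday = _holiday_factor(scenario, self.dates)
        if scenario.moratorium is not None:
            self.mask = CellMask.from_polygon(scenario.grid,
                                              scenario.moratorium.polygon(),
                                              label="moratorium")
            self.member = self.mask.boolean(self.lat, self.lon)
        else:
            self.mask = None
            self.member = np.zeros((self.nlat, self.nlon), dtype=bool)
        self.mor = _moratorium_daily(scenario, self.dates,
                                     self.member.reshape(-1))

    def seasonal_factor(self, gear: GearSpec) -> np.ndarray:
        """(12, nlat, nlon): 1 + A cos(2π(m − peak)/12)."""
        amp = _amplitude_field(gear, self.d_port)
        m = np.arange(1, 13)[:, None, None]
        return 1.0 + amp[None] * np.cos(2.0 * np.pi * (m - self.peak[None]) / 12.0)

    def daily_intensity(self, gear: GearSpec) -> np.ndarray:
        """Expected vessel-days per cell per day, shape (n_days, ncell)."""
        base = _base_field(gear, self.scenario, self.d_shore)
        seas = self.seasonal_factor(gear)           # (12, nlat, nlon)
        lam_month = (base[None] * seas).reshape(12, -1)
        month_of_day = self.dates.month.to_numpy() - 1
        lam = lam_month[month_of_day]               # (n_days, ncell)
        lam = lam * self.holiday[:, None] * self.mor
        return lam

    def expected_monthly_series(self, gear: GearSpec,
                                lam: np.ndarray | None = None) -> pd.Series:
        """Expected global daily-mean effort per month for one gear."""
        if lam is None:
            lam = self.daily_intensity(gear)
        s = pd.Series(lam.sum(axis=1), index=self.dates)
        return s.groupby(s.index.to_period("M")).mean()


# ---------------------------------------------------------------------------
# record realization
# ---------------------------------------------------------------------------

def _diff_floor(cum: np.ndarray, axis: int = 0) -> np.ndarray:
    """Integerize a cumulative array by floor, then difference back."""
    fl = np.floor(cum + 1e-9).astype(np.int64)
    out = np.empty_like(fl)
    first = [slice(None)] * fl.ndim
    first[axis] = slice(0, 1)
    out[tuple(first)] = fl[tuple(first)]
    rest = [slice(None)] * fl.ndim
    rest[axis] = slice(1, None)
    out[tuple(rest)] = np.diff(fl, axis=axis)
    return out


def _deterministic_counts(lam: np.ndarray,
                          dates: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic integer vessel-day counts for the noise-free mode.

    Monthly expected totals are integerized by error diffusion across
    cells (cumulative-floor along the cell axis), so each month's global
    realized total matches the expectation to within one vessel-day;
    each cell's monthly integer is then spread over the days of the
    month proportionally to the daily intensity.
    """
    out = np.zeros(lam.shape, dtype=np.int64)
    months = dates.to_period("M")
    for m in months.unique():
        sel = np.asarray(months == m)
        lam_m = lam[sel]                          # (days, cells)
        tot = lam_m.sum(axis=0)
        n = _diff_floor(np.cumsum(tot)[None, :], axis=1)[0]
        pos = tot > 0
        scale = np.where(pos, n / np.where(pos, tot, 1.0), 0.0)
        cum = np.cumsum(lam_m, axis=0) * scale[None, :]
        out[sel] = _diff_floor(cum, axis=0)
    return out


def _vessel_ids(gear: GearSpec, prefix: str, years: tuple) -> tuple[list, dict]:
    """Continuous-pool ids plus dropout ids mapped to their active year."""
    cont = [f"{prefix}{k:04d}" for k in range(gear.n_vessels)]
    dropout = {}
    for k in range(gear.n_dropout_vessels):
        vid = f"{prefix}D{k:03d}"
        dropout[vid] = years[k % len(years)]
    return cont, dropout


def _assign_vessels(counts: np.ndarray, dates: pd.DatetimeIndex,
                    cont: list, dropout: dict, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each vessel-day slot to a vessel.

    Per day, a random permutation of that year's pool is tiled over the
    day's slots; slots of one cell are contiguous, so vessels within a
    cell-day are distinct as long as no cell-day count exceeds the pool
    size (validated).  Returns (day_idx, cell_idx, vessel_label).
    """
    years = dates.year.to_numpy()
    pools = {y: np.array(cont + [v for v, yy in dropout.items() if yy == y],
                         dtype=object)
             for y in np.unique(years)}
    day_idx_out, cell_idx_out, vessel_out = [], [], []
    day_totals = counts.sum(axis=1)
    for d in np.flatnonzero(day_totals):
        pool = pools[years[d]]
        row = counts[d]
        active = np.flatnonzero(row)
        k = row[active]
        if k.max() > len(pool):
            raise ValueError(
                f"cell-day count {k.max()} exceeds vessel pool size "
                f"{len(pool)}; scenario infeasible"
            )
        total = int(k.sum())
        perm = rng.permutation(len(pool))
        tiled = np.resize(perm, total)
        day_idx_out.append(np.full(total, d))
        cell_idx_out.append(np.repeat(active, k))
        vessel_out.append(pool[tiled])
    if not day_idx_out:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, object))
    return (np.concatenate(day_idx_out),
            np.concatenate(cell_idx_out),
            np.concatenate(vessel_out))


def _repair_continuity(records: pd.DataFrame, cont_ids: set,
                       years: tuple) -> pd.DataFrame:
    """Ensure each continuous-pool vessel has >= 1 record per year.

    The fix swaps a vessel label on an existing record (counts are
    untouched); it is needed only in the rare case a vessel misses a
    whole year by chance.
    """
    yr = records["date"].dt.year
    have = records.assign(year=yr).groupby("vessel_id")["year"].agg(set)
    for vid in cont_ids:
        missing = set(years) - have.get(vid, set())
        for y in missing:
            pool = records.index[(yr == y) & (records["vessel_id"] != vid)]
            swapped = False
            for ix in pool[:200]:
                row = records.loc[ix]
                same_cellday = records[(records["date"] == row["date"]) &
                                       (records["lat"] == row["lat"]) &
                                       (records["lon"] == row["lon"])]
                if vid not in set(same_cellday["vessel_id"]):
                    records.loc[ix, "vessel_id"] = vid
                    swapped = True
                    break
            if not swapped:
                logger.warning("could not repair continuity for %s in %d", vid, y)
    return records


@dataclass
class SyntheticData:
    """Output bundle of the parametric generator."""

    scenario: Scenario
    vessels: pd.DataFrame
    records: pd.DataFrame
    truth: dict
    mask: CellMask | None

    def write(self, outdir) -> dict:
        """Write records/vessels CSV, truth JSON, mask GeoJSON, rasters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        rec = self.records.copy()
        rec["date"] = rec["date"].dt.strftime("%Y-%m-%d")
        paths["records"] = outdir / "records.csv"
        rec.to_csv(paths["records"], index=False)
        paths["vessels"] = outdir / "vessels.csv"
        self.vessels.to_csv(paths["vessels"], index=False)
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_json_default)
        if self.mask is not None:
            paths["mask"] = outdir / "mask.geojson"
            write_mask_geojson(self.scenario, paths["mask"])
        port, shore = generate_distance_fields(self.scenario)
        paths["port_raster"] = outdir / "port_distance.nc"
        paths["shore_raster"] = outdir / "shore_distance.nc"
        port.to_dataset(name="distance_km").to_netcdf(paths["port_raster"],
                                                      engine="scipy")
        shore.to_dataset(name="distance_km").to_netcdf(paths["shore_raster"],
                                                       engine="scipy")
        return {k: str(v) for k, v in paths.items()}


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


_GEAR_PREFIX = {
    "trawlers": "T", "fixed_gear": "F", "drifting_longlines": "L",
    "purse_coastal": "PC", "purse_high_seas": "PH",
    "squid_jigger": "J", "other": "O",
}

#: generator gear names reported as plain purse seiners in the vessel
#: table, so the downstream length/distance split is exercised
_PURSE_GEARS = {"purse_coastal": "purse_seines", "purse_high_seas": "purse_seines"}


def generate_parametric(scenario: Scenario) -> SyntheticData:
    """Generate vessel table, daily fishing records and the truth record."""
    rng = np.random.default_rng(scenario.seed)
    fields = ScenarioFields(scenario)
    dates = fields.dates
    lon_flat = fields.lon2.reshape(-1)
    lat_flat = fields.lat2.reshape(-1)

    all_records = []
    vessel_rows = []
    truth_gears = {}
    for gear in scenario.gears:
        lam = fields.daily_intensity(gear)
        if scenario.noise == "poisson":
            counts = rng.poisson(lam)
        else:
            counts = _deterministic_counts(lam, fields.dates)
        prefix = _GEAR_PREFIX.get(gear.name, gear.name[:2].upper())
        cont, dropout = _vessel_ids(gear, prefix, scenario.years)
        di, ci, vid = _assign_vessels(counts, dates, cont, dropout, rng)
        jitter_scale = 0.45 * scenario.resolution_deg
        jlon = rng.uniform(-jitter_scale, jitter_scale, size=len(di))
        jlat = rng.uniform(-jitter_scale, jitter_scale, size=len(di))
        rec = pd.DataFrame({
            "vessel_id": vid,
            "date": dates[di],
            "lat": lat_flat[ci] + jlat,
            "lon": lon_flat[ci] + jlon,
            "is_fishing": 1,
            "_gear": gear.name,
        })
        all_records.append(rec)

        lo, hi = gear.length_range
        for v in cont + list(dropout):
            vessel_rows.append({
                "vessel_id": v,
                "gear_class": _PURSE_GEARS.get(gear.name, gear.name),
                "length_m": round(float(rng.uniform(lo, hi)), 1),
                "_true_gear": gear.name,
            })
        truth_gears[gear.name] = {
            "expected_vessel_days": float(lam.sum()),
            "realized_vessel_days": int(counts.sum()),
            "amplitude": gear.amplitude,
            "n_vessels": gear.n_vessels,
            "dropout_vessels": sorted(dropout),
            "expected_monthly_series": {
                str(k): float(v)
                for k, v in fields.expected_monthly_series(gear, lam).items()
            },
        }

    records = pd.concat(all_records, ignore_index=True)
    order = np.lexsort((records["vessel_id"].to_numpy(),
                        records["date"].to_numpy()))
    records = records.iloc[order].reset_index(drop=True)
    for gear in scenario.gears:
        cont, _ = _vessel_ids(gear, _GEAR_PREFIX.get(gear.name,
                                                     gear.name[:2].upper()),
                              scenario.years)
        sub = records["_gear"] == gear.name
        if sub.any():
            fixed = _repair_continuity(records.loc[sub].copy(), set(cont),
                                       scenario.years)
            records.loc[sub, "vessel_id"] = fixed["vessel_id"].to_numpy()
    records = records.drop(columns=["_gear"])

    vessels = pd.DataFrame(vessel_rows)
    # supply the mean-shore-distance attribute from the vessels' own
    # generated fishing positions (as the real vessel table would)
    if scenario.coast_lon is not None:
        d_nm = haversine_km(scenario.coast_lon, records["lat"].to_numpy(),
                            records["lon"].to_numpy(),
                            records["lat"].to_numpy()) / KM_PER_NM
        mean_nm = pd.Series(d_nm, index=records["vessel_id"].to_numpy()
                            ).groupby(level=0).mean()
        vessels["mean_shore_distance_nm"] = (
            vessels["vessel_id"].map(mean_nm).round(1)
        )
    else:
        vessels["mean_shore_distance_nm"] = np.nan

    expected_total = sum(v["expected_vessel_days"] for v in truth_gears.values())
    truth = {
        "scenario": json.loads(json.dumps(scenario.to_dict(), default=_json_default)),
        "gears": truth_gears,
        "expected_shares_pct": {
            g: 100.0 * v["expected_vessel_days"] / expected_total
            for g, v in truth_gears.items()
        },
        "holiday_days": {str(k): float(v) for k, v in scenario.holidays.items()},
        "peak_month_field": fields.peak,
        "moratorium_cells": sorted(map(list, fields.mask.cells))
        if fields.mask else [],
        "n_records": int(len(records)),
    }
    vessels_out = vessels.drop(columns=["_true_gear"]).copy()
    truth["vessel_true_gear"] = dict(zip(vessels["vessel_id"],
                                         vessels["_true_gear"]))
    return SyntheticData(scenario=scenario, vessels=vessels_out,
                         records=records, truth=truth, mask=fields.mask)


# ---------------------------------------------------------------------------
# distance rasters and EEZ mask
# ---------------------------------------------------------------------------

def generate_distance_fields(scenario: Scenario,
                             resolution_deg: float = 0.1,
                             margin_deg: float = 1.0
                             ) -> tuple[xr.DataArray, xr.DataArray]:
    """Fine-grid (port, shore) distance rasters over the domain.

    Exact great-circle distance to the nearest synthetic port and to the
    synthetic coastline meridian; raster nodes on land (west of the
    coastline) are invalid (NaN).
    """
    if not scenario.ports:
        raise ValueError("scenario specifies no ports")
    lon = np.arange(scenario.lon_min - margin_deg,
                    scenario.lon_max + margin_deg + 1e-9, resolution_deg)
    lat = np.arange(scenario.lat_min - margin_deg,
                    scenario.lat_max + margin_deg + 1e-9, resolution_deg)
    lon2, lat2 = np.meshgrid(lon, lat)
    d_port = _port_distance_km(scenario, lon2, lat2)
    if scenario.coast_lon is not None:
        d_shore = _shore_distance_km(scenario, lon2, lat2)
        land = lon2 < scenario.coast_lon
        d_port = np.where(land, np.nan, d_port)
        d_shore = np.where(land, np.nan, d_shore)
    else:
        d_shore = d_port.copy()
        logger.warning("scenario has no coastline; shore raster defaults to "
                       "the port raster")
    coords = {"lat": lat, "lon": lon}
    return (xr.DataArray(d_port, dims=("lat", "lon"), coords=coords,
                         name="distance_km"),
            xr.DataArray(d_shore, dims=("lat", "lon"), coords=coords,
                         name="distance_km"))


def generate_eez_mask(scenario: Scenario) -> tuple[CellMask, dict]:
    """Cell mask (center-in-polygon) plus GeoJSON for the closure region."""
    if scenario.moratorium is None:
        raise ValueError("scenario has no moratorium region")
    poly = scenario.moratorium.polygon()
    mask = CellMask.from_polygon(scenario.grid, poly, label="moratorium")
    gj = {"type": "Feature", "properties": {"label": "moratorium"},
          "geometry": mapping(poly)}
    return mask, gj


def write_mask_geojson(scenario: Scenario, path) -> None:
    _, gj = generate_eez_mask(scenario)
    with open(path, "w") as fh:
        json.dump(gj, fh)


# ---------------------------------------------------------------------------
# bioeconomic mode
# ---------------------------------------------------------------------------

@dataclass
class BioeconomicParams:
    """Parameters of the effort dynamic dE/dt = κ_e(pqB − c)E − R.

    ``q`` (catchability, km²/fishing-day), ``B`` (biomass density,
    kg/km²) and ``R`` (regulatory removal, fishing-days/month/km² per
    month) may be scalars, per-cell arrays, or callables of time (days)
    returning either.  Effort is clipped at zero.
    """

    kappa_e: float = 1e-4       # per $ per day
    price: float = 2.0          # $/kg
    cost: float = 500.0         # $/fishing-day
    q: object = 0.01            # km^2 / fishing-day
    B: object = 50000.0         # kg / km^2
    R: object = 0.0             # fishing-days/month/km^2 removed per day
    E0: object = 1.0            # fishing-days/month/km^2


def _eval(param, t: float):
    value = param(t) if callable(param) else param
    return np.asarray(value, dtype=float)


def simulate_effort(params: BioeconomicParams, n_days: int,
                    dt: float = 1.0) -> np.ndarray:
    """Euler integration of the effort dynamic.

    Returns the trajectory array of shape ``(n_steps + 1, *shape(E0))``
    sampled every ``dt`` days, with E clipped at zero.
    """
    E = np.atleast_1d(np.asarray(params.E0, dtype=float)).copy()
    if not np.all(np.isfinite(E)):
        raise ValueError("non-finite initial effort")
    n_steps = int(round(n_days / dt))
    out = np.empty((n_steps + 1,) + E.shape)
    out[0] = E
    for k in range(n_steps):
        t = k * dt
        pqb = params.price * _eval(params.q, t) * _eval(params.B, t)
        growth = params.kappa_e * (pqb - params.cost) * E
        dE = growth - _eval(params.R, t)
        if not np.all(np.isfinite(dE)):
            raise ValueError(f"non-finite effort derivative at t={t}")
        E = np.maximum(0.0, E + dt * dE)
        out[k + 1] = E
    return out


def generate_bioeconomic(params: BioeconomicParams, scenario: Scenario,
                         n_days: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Integrate the effort dynamic over the scenario domain and thin the
    resulting effort density into daily vessel-day records.

    ``E`` (fishing-days/month/km²) is converted to expected vessel-days
    per cell and day via the cell area and the mean month length.
    Returns (records, truth) where truth holds the effort trajectory.
    """
    fields = ScenarioFields(scenario)
    dates = fields.dates if n_days is None else fields.dates[:n_days]
    traj = simulate_effort(params, n_days=len(dates) - 1, dt=1.0)
    area = scenario.grid.cell_area_km2()
    _, row_idx = scenario.grid.cell_index(
        np.zeros_like(fields.lat), fields.lat)
    cell_area = np.tile(area[row_idx][:, None],
                        (1, fields.nlon)).reshape(-1)
    if traj.ndim == 2 and traj.shape[1] == 1:
        lam = traj[:, 0][:, None] * cell_area[None, :] / DAYS_PER_MONTH
    else:
        lam = traj.reshape(traj.shape[0], -1) * cell_area[None, :] / DAYS_PER_MONTH
    lam = lam[:len(dates)]
    rng = np.random.default_rng(scenario.seed + 1)
    if scenario.noise == "poisson":
        counts = rng.poisson(lam)
    else:
        counts = _deterministic_counts(lam, dates)
    gear = scenario.gears[0]
    prefix = _GEAR_PREFIX.get(gear.name, gear.name[:2].upper())
    cont, dropout = _vessel_ids(gear, prefix, scenario.years)
    di, ci, vid = _assign_vessels(counts, dates, cont, dropout, rng)
    lon_flat = fields.lon2.reshape(-1)
    lat_flat = fields.lat2.reshape(-1)
    records = pd.DataFrame({
        "vessel_id": vid,
        "date": dates[di],
        "lat": lat_flat[ci],
        "lon": lon_flat[ci],
        "is_fishing": 1,
    })
    truth = {"effort_trajectory_mean": traj.reshape(traj.shape[0], -1).mean(axis=1),
             "n_records": int(len(records))}
    return records, truth
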