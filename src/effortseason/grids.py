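"""Regular longitude/latitude grids for effort rasterization.

Cells are addressed by their lower-left corner on half-open intervals
[lon, lon+res) x [lat, lat+res), with lon in [-180, 180) and lat in
[-90, 90].  Longitude 180 wraps to -180 and latitude 90 is assigned to
the northernmost row, so every point on Earth maps to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_NM = 1.852

#: Grid resolutions used in the analysis (degrees).
STUDY_RESOLUTIONS = (0.5, 1.0, 4.0)


@dataclass(frozen=True)
class GridSpec:
    """A global regular grid at ``resolution_deg`` degrees.

    The resolution must divide both 360 and 180 exactly so the grid
    tiles the globe without remainder.
    """

    resolution_deg: float

    def __post_init__(self) -> None:
        res = float(self.resolution_deg)
        if res <= 0:
            raise ValueError(f"resolution must be positive, got {res}")
        for span in (360.0, 180.0):
            n = span / res
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"resolution {res} deg does not divide {span} deg exactly"
                )

    @property
    def n_lon(self) -> int:
        return round(360.0 / self.resolution_deg)

    @property
    def n_lat(self) -> int:
        return round(180.0 / self.resolution_deg)

    @property
    def lon_edges(self) -> np.ndarray:
        return -180.0 + self.resolution_deg * np.arange(self.n_lon + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        return -90.0 + self.resolution_deg * np.arange(self.n_lat + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_edges[:-1] + self.resolution_deg / 2.0

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_edges[:-1] + self.resolution_deg / 2.0

    def wrap_lon(self, lon):
        """Map longitudes onto [-180, 180); +180 wraps to -180."""
        return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0

    def cell_index(self, lon, lat):
        """Column/row indices of the cells containing (lon, lat).

        Returns ``(col, row)`` integer arrays.  Raises on latitudes
        outside [-90, 90]; longitudes are wrapped.
        """
        lon = self.wrap_lon(lon)
        lat = np.asarray(lat, dtype=float)
        if np.any((lat < -90.0) | (lat > 90.0)):
            raise ValueError("latitude outside [-90, 90]")
        col = np.floor((lon + 180.0) / self.resolution_deg).astype(np.int64)
        row = np.floor((lat + 90.0) / self.resolution_deg).astype(np.int64)
        # lat == 90 belongs to the northernmost row
        row = np.minimum(row, self.n_lat - 1)
        return col, row

    def cell_center(self, col, row):
        """Center (lon, lat) of cells given by column/row indices."""
        col = np.asarray(col)
        row = np.asarray(row)
        lon = -180.0 + (col + 0.5) * self.resolution_deg
        lat = -90.0 + (row + 0.5) * self.resolution_deg
        return lon, lat

    def cell_area_km2(self) -> np.ndarray:
        """Cell area per latitude row (km^2), spherical Earth."""
        lat_edges = np.deg2rad(self.lat_edges)
        dlam = np.deg2rad(self.resolution_deg)
        return EARTH_RADIUS_KM**2 * dlam * np.abs(np.diff(np.sin(lat_edges)))

    def coarsen_factor(self, coarse: "GridSpec") -> int:
        """Integer block size when aggregating this grid into ``coarse``."""
        f = coarse.resolution_deg / self.resolution_deg
        if abs(f - round(f)) > 1e-9 or f < 1:
            raise ValueError(
                f"{coarse.resolution_deg} deg is not an integer multiple "
                f"of {self.resolution_deg} deg"
            )
        return round(f)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points, R = 6371 km."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
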