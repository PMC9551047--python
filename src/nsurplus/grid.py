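"""Regular lat/lon grids, cell areas and region masks.

A :class:`GridSpec` describes a rectangular grid of cell centres stored
north-to-south.  Cell areas are computed from spherical geometry per
latitude band, in hectares, because every downstream budget works in
extensive units (kg per cell) and per-hectare rates need real areas.
Each cell carries an integer country id (0 = sea / outside the domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

#: square metres per hectare
M2_PER_HA = 10_000.0


def spherical_cell_area_ha(lat_centers: np.ndarray, resolution: float) -> np.ndarray:
    """Area (ha) of a ``resolution`` x ``resolution`` degree cell per latitude band.

    Uses the exact band formula A = R^2 * dlon * (sin(lat+d/2) - sin(lat-d/2)).
    """
    lat = np.asarray(lat_centers, dtype=float)
    half = np.deg2rad(resolution / 2.0)
    dlon = np.deg2rad(resolution)
    band = np.sin(np.deg2rad(lat) + half) - np.sin(np.deg2rad(lat) - half)
    return EARTH_RADIUS_M**2 * dlon * band / M2_PER_HA


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lat/lon grid with per-cell area and country membership.

    Attributes
    ----------
    lat_centers, lon_centers:
        Cell-centre coordinates in degrees.  Latitudes strictly decreasing
        (north-to-south), longitudes strictly increasing.
    cell_area:
        Flattened (n_lat * n_lon) physical cell area in hectares.
    country_id:
        Flattened integer country id per cell; 0 means sea/outside.
    resolution:
        Grid spacing in degrees.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_area: np.ndarray
    country_id: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, float)
        lon = np.asarray(self.lon_centers, float)
        if lat.ndim != 1 or lon.ndim != 1:
            raise ValueError("lat/lon centers must be 1-D")
        if len(lat) > 1 and not np.all(np.diff(lat) < 0):
            raise ValueError("lat_centers must be strictly decreasing (north-to-south)")
        if len(lon) > 1 and not np.all(np.diff(lon) > 0):
            raise ValueError("lon_centers must be strictly increasing")
        if np.any(np.asarray(self.cell_area) <= 0):
            raise ValueError("cell_area must be strictly positive")
        if self.country_id.shape != (len(lat) * len(lon),):
            raise ValueError("country_id must be flattened to n_lat*n_lon")

    @property
    def n_lat(self) -> int:
        return len(self.lat_centers)

    @property
    def n_lon(self) -> int:
        return len(self.lon_centers)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def is_land(self) -> np.ndarray:
        return self.country_id > 0

    @property
    def countries(self) -> np.ndarray:
        """Sorted ids of countries present on the grid (excluding sea)."""
        ids = np.unique(self.country_id)
        return ids[ids > 0]

    def cells_of(self, country: int) -> np.ndarray:
        """Flat indices of cells belonging to ``country``, row-major order."""
        return np.flatnonzero(self.country_id == country)

    def to_2d(self, flat: np.ndarray) -> np.ndarray:
        return np.asarray(flat).reshape(self.n_lat, self.n_lon)

    @classmethod
    def regular(
        cls,
        n_lat: int,
        n_lon: int,
        *,
        lat_north: float = 60.0,
        lon_west: float = 0.0,
        resolution: float = 0.5,
        country_id: np.ndarray | None = None,
    ) -> "GridSpec":
        """Build a regular grid from its north-west corner cell centre."""
        lat = lat_north - resolution * np.arange(n_lat)
        lon = lon_west + resolution * np.arange(n_lon)
        band = spherical_cell_area_ha(lat, resolution)
        area = np.repeat(band, n_lon)
        if country_id is None:
            country_id = np.ones(n_lat * n_lon, dtype=int)
        return cls(lat, lon, area, np.asarray(country_id, dtype=int), resolution)


@dataclass(frozen=True)
class RegionMask:
    """Partition of land cells into named regions (NUTS-like or basins).

    ``region_id`` assigns every cell to exactly one region per scheme; 0 is
    reserved for cells outside the scheme (sea).
    """

    scheme: str
    region_id: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = np.unique(self.region_id)
        for r in ids[ids > 0]:
            if int(r) not in self.labels:
                self.labels[int(r)] = f"{self.scheme}_{int(r):03d}"

    @property
    def regions(self) -> np.ndarray:
        ids = np.unique(self.region_id)
        return ids[ids > 0]

    @classmethod
    def from_countries(cls, grid: GridSpec, scheme: str = "NUTS0") -> "RegionMask":
        return cls(scheme, grid.country_id.copy())


def ring_neighbours(grid: GridSpec, cell: int, radius: int) -> np.ndarray:
    """Flat indices of the Chebyshev ring at ``radius`` around ``cell``.

    Row-major ordering within the ring; indices outside the grid are dropped.
    """
    r0, c0 = divmod(cell, grid.n_lon)
    out: list[int] = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if max(abs(dr), abs(dc)) != radius:
                continue
            r, c = r0 + dr, c0 + dc
            if 0 <= r < grid.n_lat and 0 <= c < grid.n_lon:
                out.append(r * grid.n_lon + c)
    return np.asarray(out, dtype=int)
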