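"""Latitude-longitude grid geometry, gridded fields, region masks, and I/O.

All surfaces in a run live on a single uniform cell-centered lat-lon
:class:`GridSpec`; mixing grids raises rather than silently regridding.
Cells are indexed row-major with latitude as the outer dimension
(south-to-north rows) and longitude inner (west-to-east, [-180, 180)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

#: Authalic Earth radius in km; fixes the sphere all cell areas refer to.
EARTH_RADIUS_KM = 6371.0

REGION_NAMES = (
    "Africa",
    "North America",
    "Europe",
    "Asia",
    "South America",
    "Oceania",
)

#: Region id for ocean / unassigned cells.
OCEAN = -1


class GridError(ValueError):
    """Invalid grid definition or grid mismatch between surfaces."""


class FieldIOError(ValueError):
    """Malformed gridded-field file."""


@dataclass(frozen=True)
class GridSpec:
    """Uniform global cell-centered latitude-longitude grid.

    Latitude spacing is 180/n_lat degrees, longitude spacing 360/n_lon;
    centers are strictly increasing, latitudes in (-90, 90), longitudes
    in [-180, 180).
    """

    n_lat: int
    n_lon: int

    def __post_init__(self) -> None:
        if self.n_lat < 2 or self.n_lon < 2:
            raise GridError(f"grid dimensions must be >= 2, got {self.n_lat}x{self.n_lon}")
        if self.n_lat % 2 or self.n_lon % 2:
            raise GridError(f"grid dimensions must be even, got {self.n_lat}x{self.n_lon}")

    @property
    def dlat(self) -> float:
        return 180.0 / self.n_lat

    @property
    def dlon(self) -> float:
        return 360.0 / self.n_lon

    @property
    def lat_centers(self) -> np.ndarray:
        return -90.0 + self.dlat * (np.arange(self.n_lat) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        return -180.0 + self.dlon * (np.arange(self.n_lon) + 0.5)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def cell_index(self, i_lat: int, i_lon: int) -> int:
        """Row-major flat index (lat outer, lon inner)."""
        return i_lat * self.n_lon + i_lon


def make_grid(n_lat: int, n_lon: int) -> GridSpec:
    """Build a uniform global grid; the default configuration 64 x 128
    approximates the 2.8 degree resolution of global chemical transport
    models (spacing 2.8125 degrees)."""
    return GridSpec(n_lat=n_lat, n_lon=n_lon)


@dataclass
class GriddedField:
    """One scalar per grid cell, with a units tag; missing cells are NaN."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "GriddedField":
        return GriddedField(self.grid, self.values.copy(), self.units)


def require_same_grid(*fields) -> GridSpec:
    """All surfaces in one computation must share one GridSpec."""
    grids = {f.grid for f in fields}
    if len(grids) != 1:
        raise GridError(f"fields on mismatched grids: {sorted((g.n_lat, g.n_lon) for g in grids)}")
    return fields[0].grid


def cell_areas(grid: GridSpec) -> GriddedField:
    """Spherical-quadrilateral cell areas in km^2.

    area = R^2 * dlon * (sin(lat_north) - sin(lat_south)); the sum over the
    globe is exactly 4 pi R^2 (~5.101e8 km^2).
    """
    edges = np.radians(-90.0 + grid.dlat * np.arange(grid.n_lat + 1))
    band = np.sin(edges[1:]) - np.sin(edges[:-1])
    dlon_rad = np.radians(grid.dlon)
    areas = EARTH_RADIUS_KM**2 * dlon_rad * band[:, None] * np.ones((1, grid.n_lon))
    return GriddedField(grid, areas, units="km2")


@dataclass
class RegionMap:
    """Per-cell region assignment over the six continental regions.

    ``region_ids`` holds an index into :data:`REGION_NAMES` for land cells
    and :data:`OCEAN` (-1) for ocean cells.
    """

    grid: GridSpec
    region_ids: np.ndarray
    names: tuple[str, ...] = field(default=REGION_NAMES)

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.region_ids.shape != self.grid.shape:
            raise GridError("region map shape does not match grid")
        bad = (self.region_ids < OCEAN) | (self.region_ids >= len(self.names))
        if bad.any():
            raise GridError("region ids out of range")

    @property
    def land(self) -> np.ndarray:
        return self.region_ids != OCEAN

    def mask(self, name: str) -> np.ndarray:
        return self.region_ids == self.names.index(name)


# ---------------------------------------------------------------------------
# NetCDF I/O (one variable per field; CF-style "units" attribute required)


def write_field(fld: GriddedField, path: str | Path, name: str = "field") -> None:
    grid = fld.grid
    ds = xr.Dataset(
        {name: (("lat", "lon"), fld.values, {"units": fld.units})},
        coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
    )
    ds.to_netcdf(path, engine="scipy")


def read_field(path: str | Path, name: str = "field", grid: GridSpec | None = None) -> GriddedField:
    with xr.open_dataset(path, engine="scipy") as ds:
        if name not in ds:
            raise FieldIOError(f"variable {name!r} not found in {path}")
        var = ds[name]
        if "units" not in var.attrs:
            raise FieldIOError(f"variable {name!r} is missing its units attribute")
        values = np.asarray(var.values, dtype=float)
    if values.ndim != 2:
        raise FieldIOError(f"variable {name!r} is not a (lat, lon) surface")
    n_lat, n_lon = values.shape
    if grid is None:
        grid = make_grid(n_lat, n_lon)
    elif (n_lat, n_lon) != grid.shape:
        raise FieldIOError(
            f"variable {name!r}: dimensions {values.shape} do not match expected grid {grid.shape}"
        )
    return GriddedField(grid, values, units=str(var.attrs["units"]))


def roundtrip_field(fld: GriddedField, path: str | Path, name: str = "field") -> GriddedField:
    """Write then read back; the result equals the input to representation
    precision, with units and missing mask preserved."""
    write_field(fld, path, name=name)
    return read_field(path, name=name, grid=fld.grid)


def write_monthly(values: np.ndarray, grid: GridSpec, path: str | Path,
                  name: str = "field", units: str = "") -> None:
    """Write a (12, lat, lon) monthly bundle as one NetCDF variable."""
    ds = xr.Dataset(
        {name: (("month", "lat", "lon"), np.asarray(values, dtype=float), {"units": units})},
        coords={"month": np.arange(1, 13), "lat": grid.lat_centers, "lon": grid.lon_centers},
    )
    ds.to_netcdf(path, engine="scipy")


def read_monthly(path: str | Path, name: str = "field", grid: GridSpec | None = None) -> np.ndarray:
    with xr.open_dataset(path, engine="scipy") as ds:
        if name not in ds:
            raise FieldIOError(f"variable {name!r} not found in {path}")
        values = np.asarray(ds[name].values, dtype=float)
    if values.ndim != 3 or values.shape[0] != 12:
        raise FieldIOError(f"variable {name!r} is not a (month, lat, lon) bundle")
    if grid is not None and values.shape[1:] != grid.shape:
        raise FieldIOError(
            f"variable {name!r}: dimensions {values.shape[1:]} do not match grid {grid.shape}"
        )
    return values
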