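"""Shared grid/time conventions and raster, gridded-time-series and vector I/O.

Conventions used throughout the package:

* regular lat/lon grids, cell-centre registration, longitudes in [-180, 180);
* the internal time base is the calendar year — monthly inputs are collapsed
  to annual means with equal month weights;
* a censored time of emergence is stored as ``horizon_year + 1`` internally
  and rendered as ``">{horizon}"`` in reports;
* NetCDF files are CF-style (lat/lon/time or lat/lon/year) NETCDF3, GeoTIFFs
  carry minimal EPSG:4326 georeferencing, regions travel as GeoJSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
import xarray as xr
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from ._geo import cell_areas_km2, cell_edges

logger = logging.getLogger(__name__)

#: the four seafloor climate drivers of the hazard analysis
DRIVERS = ("temperature", "oxygen", "ph", "poc_flux")

#: direction in which a change in each driver is harmful to benthic fauna:
#: warming is harmful (+1); oxygen loss, acidification and declining POC flux
#: are harmful as decreases (-1)
HARMFUL_SIGN = {"temperature": 1.0, "oxygen": -1.0, "ph": -1.0, "poc_flux": -1.0}

SCENARIOS = ("historical", "rcp26", "rcp85", "control")

DEFAULT_UNITS = {
    "temperature": "degC",
    "oxygen": "mol m-3",
    "ph": "pH (total scale)",
    "poc_flux": "mgC m-2 d-1",
}

REGION_CATEGORIES = (
    "exploration_contract",
    "reserved_area",
    "apei",
    "ridge_buffer",
    "rfmo_area",
    "vme",
    "custom",
)

#: documented fill value for censored / invalid cells in raster files
FILL_VALUE = -9999.0


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


class FormatError(ValueError):
    """Raised when a file does not have the expected structure."""


def _strictly_monotonic(a: np.ndarray) -> bool:
    d = np.diff(a)
    return bool(np.all(d > 0) or np.all(d < 0))


@dataclass(frozen=True)
class Grid:
    """A regular geographic grid, cell-centre registered.

    Parameters
    ----------
    lat : array of latitude centres, degrees north, strictly monotonic.
    lon : array of longitude centres, degrees east in [-180, 180),
        strictly monotonic.
    """

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        for name, ax in (("lat", lat), ("lon", lon)):
            if ax.ndim != 1 or ax.size == 0:
                raise ValidationError(f"{name} axis must be a non-empty 1-D array")
            if np.unique(ax).size != ax.size:
                raise ValidationError(f"duplicate coordinates on {name} axis")
            if ax.size > 1 and not _strictly_monotonic(ax):
                raise ValidationError(f"{name} axis must be strictly monotonic")
        if lat.min() < -90 or lat.max() > 90:
            raise ValidationError("latitudes must lie in [-90, 90]")
        if lon.min() < -180 or lon.max() >= 180:
            raise ValidationError("longitudes must lie in [-180, 180)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical cell areas, km², shape (nlat, nlon), strictly positive."""
        areas = cell_areas_km2(self.lat, self.lon)
        return areas

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) cell-centre meshes, each (nlat, nlon)."""
        lon2d, lat2d = np.meshgrid(self.lon, self.lat)
        return lon2d, lat2d

    def lat_edges(self) -> np.ndarray:
        return cell_edges(self.lat)

    def lon_edges(self) -> np.ndarray:
        return cell_edges(self.lon)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Grid)
                and np.array_equal(self.lat, other.lat)
                and np.array_equal(self.lon, other.lon))


def regular_grid(nlat: int, nlon: int,
                 lat_range=(-60.0, 60.0), lon_range=(-180.0, 179.0)) -> Grid:
    """Convenience constructor for an evenly spaced cell-centre grid."""
    lat = np.linspace(lat_range[0], lat_range[1], nlat)
    lon = np.linspace(lon_range[0], lon_range[1], nlon)
    return Grid(lat=lat, lon=lon)


@dataclass
class ClimateCube:
    """Annual gridded time series of one driver under one scenario.

    values has shape (nyears, nlat, nlon); mask is a per-cell boolean
    (True = land/invalid) applied to every year.
    """

    driver: str
    scenario: str
    model_id: str
    grid: Grid
    years: np.ndarray
    values: np.ndarray
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self):
        if self.driver not in DRIVERS:
            raise ValidationError(f"unknown driver {self.driver!r}; allowed: {DRIVERS}")
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; allowed: {SCENARIOS}")
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1:
            raise ValidationError("years must be 1-D")
        if np.any(np.diff(self.years) != 1):
            raise ValidationError("years must be contiguous, strictly increasing")
        expected = (self.years.size,) + self.grid.shape
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != (years, lat, lon) {expected}")
        if self.mask is None:
            self.mask = ~np.all(np.isfinite(self.values), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValidationError("mask shape must match grid")
        if not self.units:
            self.units = DEFAULT_UNITS.get(self.driver, "")
        valid = ~self.mask
        if not np.all(np.isfinite(self.values[:, valid])):
            raise ValidationError("non-finite values on unmasked cells")

    def select_years(self, start: int, end: int) -> "ClimateCube":
        """Sub-cube for the inclusive year window [start, end]."""
        if start < self.years[0] or end > self.years[-1]:
            raise ValidationError(
                f"window ({start}, {end}) not covered by years "
                f"[{self.years[0]}, {self.years[-1]}]")
        sel = (self.years >= start) & (self.years <= end)
        return replace(self, years=self.years[sel], values=self.values[sel])


@dataclass
class Field2D:
    """A per-cell 2-D field with optional censoring (used for ToE rasters)."""

    grid: Grid
    values: np.ndarray
    name: str = "field"
    units: str = ""
    censored: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.censored is not None:
            self.censored = np.asarray(self.censored, dtype=bool)
            if self.censored.shape != self.grid.shape:
                raise ValidationError("censored mask shape must match grid")


@dataclass
class Region:
    name: str
    category: str
    geometry: BaseGeometry

    def __post_init__(self):
        if self.category not in REGION_CATEGORIES:
            raise ValidationError(
                f"unknown region category {self.category!r}; "
                f"allowed: {REGION_CATEGORIES}")


@dataclass
class RegionSet:
    """Named, categorised polygons in geographic WGS84 coordinates."""

    regions: list[Region]

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate region names: {dupes}")

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def get(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def by_category(self, category: str) -> list[Region]:
        return [r for r in self.regions if r.category == category]


# ---------------------------------------------------------------------------
# NetCDF climate cubes
# ---------------------------------------------------------------------------

def write_climate_cube(cube: ClimateCube, path) -> None:
    """Write a cube as CF-style NetCDF (annual time axis named 'year')."""
    vals = np.where(cube.mask[None, :, :], np.nan, cube.values)
    da = xr.DataArray(
        vals,
        dims=("year", "lat", "lon"),
        coords={
            "year": cube.years.astype(np.int32),
            "lat": cube.grid.lat,
            "lon": cube.grid.lon,
        },
        name=cube.driver,
        attrs={"units": cube.units, "scenario": cube.scenario,
               "model_id": cube.model_id, "driver": cube.driver},
    )
    ds = da.to_dataset()
    ds.attrs["Conventions"] = "CF-1.8"
    ds.to_netcdf(path, engine="scipy")


def _annualize(da: xr.DataArray) -> xr.DataArray:
    """Collapse a monthly (datetime-indexed) series to annual means.

    Months are weighted equally — the time base of the analysis is the
    'annual climate condition', and ESM calendars (e.g. 360-day) make
    day-length weighting ill-defined anyway.
    """
    annual = da.groupby("time.year").mean("time")
    return annual


def read_climate_cube(path, driver: str, variable_name: str | None = None,
                      scenario: str = "historical",
                      model_id: str = "unknown") -> ClimateCube:
    """Read a NetCDF gridded series into a :class:`ClimateCube`.

    Accepts either an annual file (integer ``year`` coordinate) or a monthly
    CF-time file, which is collapsed to annual means. The cell mask is derived
    from fill values (NaN after CF decoding).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = xr.open_dataset(path)
    try:
        var = variable_name or driver
        if var not in ds:
            raise FormatError(
                f"variable {var!r} not found in {path.name}; "
                f"present: {sorted(ds.data_vars)}")
        da = ds[var]
        if "year" in da.dims:
            da = da.transpose("year", "lat", "lon")
            years = da["year"].values.astype(int)
            values = da.values.astype(float)
        elif "time" in da.dims:
            da = da.transpose("time", "lat", "lon")
            da = _annualize(da)
            years = da["year"].values.astype(int)
            values = da.values.astype(float)
        else:
            raise FormatError(f"variable {var!r} lacks a time/year dimension")
        lat = ds["lat"].values.astype(float)
        lon = ds["lon"].values.astype(float)
        if lat.size > 1 and not _strictly_monotonic(lat):
            raise ValidationError(f"non-monotonic lat axis in {path.name}")
        if lon.size > 1 and not _strictly_monotonic(lon):
            raise ValidationError(f"non-monotonic lon axis in {path.name}")
        attrs = dict(da.attrs) | dict(ds[var].attrs)
        cube = ClimateCube(
            driver=driver,
            scenario=str(attrs.get("scenario", scenario)),
            model_id=str(attrs.get("model_id", model_id)),
            grid=Grid(lat=lat, lon=lon),
            years=years,
            values=values,
            units=str(attrs.get("units", "")),
        )
        return cube
    finally:
        ds.close()


# ---------------------------------------------------------------------------
# 2-D fields: NetCDF and GeoTIFF
# ---------------------------------------------------------------------------

def write_field(fld: Field2D, path, format: str = "NetCDF",
                fill_value: float = FILL_VALUE) -> None:
    """Write a 2-D field georeferenced; censored cells become ``fill_value``."""
    values = fld.values.copy()
    if fld.censored is not None:
        values = np.where(fld.censored, fill_value, values)
    values = np.where(np.isfinite(values), values, fill_value)
    if format == "NetCDF":
        da = xr.DataArray(
            values, dims=("lat", "lon"),
            coords={"lat": fld.grid.lat, "lon": fld.grid.lon},
            name=fld.name or "field",
            attrs={"units": fld.units, "_FillValue_doc": fill_value,
                   **{k: v for k, v in fld.attrs.items()
                      if isinstance(v, (str, int, float))}},
        )
        da.encoding["_FillValue"] = None
        da.to_dataset().to_netcdf(path, engine="scipy")
    elif format == "GeoTIFF":
        _write_geotiff(fld.grid, values, path, fill_value)
    else:
        raise ValidationError(f"unknown format {format!r}; allowed: NetCDF, GeoTIFF")


def _write_geotiff(grid: Grid, values: np.ndarray, path, fill_value: float) -> None:
    # GeoTIFF rows run north -> south; flip if the lat axis is ascending.
    lat, data = grid.lat, values
    if lat[0] < lat[-1] if lat.size > 1 else False:
        data = data[::-1, :]
        lat = lat[::-1]
    dlat = abs(float(lat[0] - lat[1])) if lat.size > 1 else 1.0
    dlon = abs(float(grid.lon[1] - grid.lon[0])) if grid.lon.size > 1 else 1.0
    west_edge = float(grid.lon.min()) - dlon / 2.0
    north_edge = float(lat[0]) + dlat / 2.0
    # minimal EPSG:4326 GeoTIFF keys: geographic model, pixel-is-area, WGS84
    geokeys = (1, 1, 0, 3,
               1024, 0, 1, 2,
               1025, 0, 1, 1,
               2048, 0, 1, 4326)
    extratags = [
        (33550, "d", 3, (dlon, dlat, 0.0)),                     # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, west_edge, north_edge, 0.0)),  # tiepoint
        (34735, "H", len(geokeys), geokeys),                    # GeoKeyDirectory
        (42113, "s", 0, str(fill_value)),                       # GDAL_NODATA
    ]
    tifffile.imwrite(path, data.astype(np.float64), extratags=extratags)


def read_field(path, format: str | None = None, name: str | None = None,
               fill_value: float = FILL_VALUE,
               censored_as: str = "censored") -> Field2D:
    """Read a 2-D field written by :func:`write_field`.

    Cells equal to the fill value are restored as censored (``censored_as ==
    "censored"``, the default) or as NaN.
    """
    path = Path(path)
    if format is None:
        format = "GeoTIFF" if path.suffix.lower() in (".tif", ".tiff") else "NetCDF"
    if format == "NetCDF":
        ds = xr.open_dataset(path)
        try:
            var = name or next(iter(ds.data_vars))
            da = ds[var]
            grid = Grid(lat=ds["lat"].values.astype(float),
                        lon=ds["lon"].values.astype(float))
            values = da.values.astype(float)
            units = str(da.attrs.get("units", ""))
        finally:
            ds.close()
    elif format == "GeoTIFF":
        grid, values = _read_geotiff(path)
        units = ""
    else:
        raise ValidationError(f"unknown format {format!r}")
    filled = values == fill_value
    if censored_as == "censored":
        censored = filled
    else:
        values = np.where(filled, np.nan, values)
        censored = None
    return Field2D(grid=grid, values=values, name=name or "field",
                   units=units, censored=censored)


def _read_geotiff(path) -> tuple[Grid, np.ndarray]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    try:
        dlon, dlat = tags[33550][0], tags[33550][1]
        west_edge, north_edge = tags[33922][3], tags[33922][4]
    except KeyError:
        raise FormatError(f"{path} lacks GeoTIFF georeferencing tags") from None
    nlat, nlon = data.shape
    lon = west_edge + dlon / 2.0 + dlon * np.arange(nlon)
    lat = north_edge - dlat / 2.0 - dlat * np.arange(nlat)  # north -> south
    # internal convention: ascending latitude axis
    return Grid(lat=lat[::-1], lon=lon), data[::-1, :]


# ---------------------------------------------------------------------------
# GeoJSON regions
# ---------------------------------------------------------------------------

def read_regions(path) -> RegionSet:
    """Read a GeoJSON FeatureCollection of named, categorised polygons.

    Invalid rings (e.g. self-intersecting bowties) are repaired with
    ``make_valid`` and the repair is logged as a warning.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    regions = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        name = props.get("name")
        category = props.get("category")
        if name is None or category is None:
            raise FormatError("every feature needs 'name' and 'category' properties")
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            repaired = make_valid(geom)
            logger.warning("repaired invalid geometry for region %r", name)
            warnings.warn(f"repaired invalid geometry for region {name!r}",
                          stacklevel=2)
            geom = repaired
        regions.append(Region(name=name, category=category, geometry=geom))
    return RegionSet(regions=regions)


def write_regions(region_set: RegionSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": r.name, "category": r.category},
            "geometry": shapely_mapping(r.geometry),
        }
        for r in region_set
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def censored_label(horizon: int = 2100) -> str:
    """How a censored emergence year is rendered in reports."""
    return f">{horizon}"
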