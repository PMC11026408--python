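"""Gridded temperature I/O and remapping.

Reads CF-style NetCDF files (time x lat x lon) into :class:`TemperatureCube`
objects with validated grid geometry, writes them back, remaps between
regular lat-lon grids with bilinear interpolation, and serializes summary
tables to CSV/JSON.

All NetCDF access goes through xarray's scipy backend (NetCDF3), which
keeps files plain and portable.  Monthly inputs are averaged to annual
means on read: every downstream statistic is defined on annual data.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .grid import Grid, cell_area_weights

_NC_ENGINE = "scipy"

_LAT_NAMES = ("lat", "latitude")
_LON_NAMES = ("lon", "longitude")
_TIME_NAMES = ("time", "year")


@dataclass
class TemperatureCube:
    """One ensemble member's annual-mean gridded temperature series.

    values are Kelvin with dims (time, lat, lon), defined everywhere:
    2-m temperature exists over both land and ocean, so masks enter only
    in statistics, never in field computation.
    """

    grid: Grid
    years: np.ndarray  # consecutive integer calendar years
    values: np.ndarray  # K, shape (nyears, nlat, nlon)
    member_id: str = "member_0"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.years.size, *self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.years.size} years on grid {self.grid.shape}"
            )
        if self.years.size > 1 and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature cube contains missing/non-finite values")

    def select_years(self, start: int, end: int) -> "TemperatureCube":
        """Subset to the inclusive year range [start, end]."""
        if start < self.years[0] or end > self.years[-1]:
            raise ValueError(
                f"window {start}-{end} not covered by cube years "
                f"{self.years[0]}-{self.years[-1]}"
            )
        sel = (self.years >= start) & (self.years <= end)
        return TemperatureCube(self.grid, self.years[sel], self.values[sel], self.member_id)


@dataclass
class SurfaceMask:
    """Land fraction in [0, 1] per cell; a cell is 'land' when the
    fraction reaches ``cutoff`` (coastal cells are fractional)."""

    grid: Grid
    land_fraction: np.ndarray
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        self.land_fraction = np.asarray(self.land_fraction, dtype=float)
        if self.land_fraction.shape != self.grid.shape:
            raise ValueError("land_fraction shape does not match grid")
        if np.any(self.land_fraction < 0) or np.any(self.land_fraction > 1):
            raise ValueError("land_fraction must lie in [0, 1]")

    def is_land(self) -> np.ndarray:
        return self.land_fraction >= self.cutoff

    def is_ocean(self) -> np.ndarray:
        return ~self.is_land()

    def domain_mask(self, domain: str) -> np.ndarray:
        """Boolean cell mask for 'land', 'ocean' or 'global'."""
        if domain == "land":
            return self.is_land()
        if domain == "ocean":
            return self.is_ocean()
        if domain == "global":
            return np.ones(self.grid.shape, dtype=bool)
        raise ValueError(f"unknown domain {domain!r}")


def _find_coord(ds: xr.Dataset, candidates: Sequence[str], kind: str) -> str:
    for name in candidates:
        if name in ds.coords or name in ds.variables:
            return name
    raise ValueError(f"file has no {kind} coordinate (looked for {candidates})")


def _to_kelvin(values: np.ndarray, units: str) -> np.ndarray:
    u = units.strip().lower()
    if u in ("k", "kelvin", "degk", "deg_k", ""):
        return values
    if u in ("degc", "c", "celsius", "deg_c", "degrees_celsius", "°c"):
        return values + 273.15
    raise ValueError(f"unsupported temperature units {units!r}")


def _annualize(time_vals: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a time axis to integer calendar years.

    Accepts datetime64 (grouped by calendar year) or numeric time
    (integer years, or fractional years with 12 samples per year).
    Monthly records are averaged with equal weight per month.
    """
    if np.issubdtype(time_vals.dtype, np.datetime64):
        years = time_vals.astype("datetime64[Y]").astype(int) + 1970
    else:
        years = np.floor(np.asarray(time_vals, dtype=float) + 1e-9).astype(int)
    uniq, inverse, counts = np.unique(years, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        order = np.argsort(years)
        return years[order], data[order]
    if not np.all(counts == counts[0]):
        raise ValueError("time axis mixes annual and sub-annual sampling")
    out = np.zeros((uniq.size, *data.shape[1:]))
    np.add.at(out, inverse, data)
    out /= counts[0]
    return uniq, out


def read_temperature(path: str | Path, varname: str = "t2m") -> TemperatureCube:
    """Read one member's temperature series from a CF-style NetCDF file.

    Monthly files (12 records per calendar year) are averaged to annual
    means, each month weighted equally.  Temperatures in Celsius are
    converted to Kelvin from the variable's units attribute.
    """
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        ds = ds.load()
    if varname not in ds:
        raise ValueError(f"variable {varname!r} not in file (has {list(ds.data_vars)})")
    da = ds[varname]
    lat_name = _find_coord(ds, _LAT_NAMES, "latitude")
    lon_name = _find_coord(ds, _LON_NAMES, "longitude")
    time_name = _find_coord(ds, _TIME_NAMES, "time")
    da = da.transpose(time_name, lat_name, lon_name)

    lat = np.asarray(ds[lat_name].values, dtype=float)
    lon = np.asarray(ds[lon_name].values, dtype=float)
    values = np.asarray(da.values, dtype=float)
    if lat.size > 1 and lat[0] > lat[-1]:  # canonicalize to ascending latitude
        lat = lat[::-1]
        values = values[:, ::-1, :]
    grid = Grid(lat, lon)

    values = _to_kelvin(values, str(da.attrs.get("units", "K")))
    years, annual = _annualize(np.asarray(ds[time_name].values), values)
    member = str(ds.attrs.get("member_id", da.attrs.get("member_id", Path(path).stem)))
    return TemperatureCube(grid, years, annual, member)


def write_temperature(cube: TemperatureCube, path: str | Path, varname: str = "t2m") -> Path:
    """Write a cube to CF-style NetCDF (annual records, units K)."""
    ds = xr.Dataset(
        {
            varname: (
                ("time", "lat", "lon"),
                cube.values,
                {"units": "K", "long_name": "2-m air temperature", "member_id": cube.member_id},
            )
        },
        coords={
            "time": ("time", cube.years.astype(np.int32), {"units": "year"}),
            "lat": ("lat", cube.grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", cube.grid.lon_centers, {"units": "degrees_east"}),
        },
        attrs={"Conventions": "CF-1.8", "member_id": cube.member_id},
    )
    path = Path(path)
    ds.to_netcdf(path, engine=_NC_ENGINE)
    return path


def write_mask(mask: SurfaceMask, path: str | Path, varname: str = "landfrac") -> Path:
    ds = xr.Dataset(
        {varname: (("lat", "lon"), mask.land_fraction, {"units": "1"})},
        coords={
            "lat": ("lat", mask.grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", mask.grid.lon_centers, {"units": "degrees_east"}),
        },
    )
    path = Path(path)
    ds.to_netcdf(path, engine=_NC_ENGINE)
    return path


def read_mask(path: str | Path, varname: str = "landfrac", cutoff: float = 0.5) -> SurfaceMask:
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        ds = ds.load()
    lat_name = _find_coord(ds, _LAT_NAMES, "latitude")
    lon_name = _find_coord(ds, _LON_NAMES, "longitude")
    lat = np.asarray(ds[lat_name].values, dtype=float)
    frac = np.asarray(ds[varname].transpose(lat_name, lon_name).values, dtype=float)
    if lat.size > 1 and lat[0] > lat[-1]:
        lat = lat[::-1]
        frac = frac[::-1]
    return SurfaceMask(Grid(lat, np.asarray(ds[lon_name].values, float)), frac, cutoff)


def remap_bilinear(cube: TemperatureCube, target: Grid) -> TemperatureCube:
    """Bilinearly remap a cube onto a target regular lat-lon grid.

    Longitude wraps periodically; latitudes beyond the source row range
    are clamped to the nearest edge row (replicate extrapolation), so
    values are always bounded by local source extremes.
    """
    src = cube.grid
    if target.dlat_deg < src.dlat_deg / 4 or target.dlon_deg < src.dlon_deg / 4:
        warnings.warn(
            "target grid is more than 4x finer than the source; "
            "bilinear interpolation cannot add information at that scale",
            stacklevel=2,
        )
    # pad longitude by one wrapped column on each side
    lon_src = np.unwrap(np.deg2rad(src.lon_centers))
    lon_pad = np.concatenate(
        [[lon_src[0] - np.deg2rad(src.dlon_deg)], lon_src, [lon_src[-1] + np.deg2rad(src.dlon_deg)]]
    )
    lat_src = src.lat_centers

    lon_t = np.deg2rad(target.lon_centers)
    # map target lons into the padded source interval
    span = 2 * np.pi
    lon_t = lon_pad[0] + np.mod(lon_t - lon_pad[0], span)
    lat_t = np.clip(target.lat_centers, lat_src[0], lat_src[-1])
    pts_lat, pts_lon = np.meshgrid(lat_t, lon_t, indexing="ij")
    pts = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])

    out = np.empty((cube.years.size, *target.shape))
    for k in range(cube.years.size):
        field = cube.values[k]
        padded = np.concatenate([field[:, -1:], field, field[:, :1]], axis=1)
        interp = RegularGridInterpolator(
            (lat_src, lon_pad), padded, method="linear", bounds_error=False, fill_value=None
        )
        out[k] = interp(pts).reshape(target.shape)
    return TemperatureCube(target, cube.years, out, cube.member_id)


def write_summary(obj, path: str | Path) -> Path:
    """Serialize an exposure summary (or any DataFrame-like) to CSV, or a
    nested scenario summary (dataclass / dict / list) to JSON.

    Column order is deterministic; floats use Python's shortest
    round-trip repr so a read-back restores values bit-identically.
    """
    path = Path(path)
    df = getattr(obj, "to_frame", None)
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif callable(df):
        df = obj.to_frame()
    if isinstance(df, pd.DataFrame):
        df.to_csv(path, index=False)
        return path

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True) + "\n")
    return path


def read_summary(path: str | Path):
    """Inverse of :func:`write_summary` (CSV -> DataFrame, JSON -> dict/list)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    return json.loads(path.read_text())


def area_weights_for(grid: Grid, mask_cells: np.ndarray | None = None) -> np.ndarray:
    """cos-lat area weights normalized to sum to 1 over the given cells."""
    w = cell_area_weights(grid)
    if mask_cells is not None:
        w = np.where(mask_cells, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("empty domain: no cells with positive weight")
    return w / total
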