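"""Regular latitude-longitude grid geometry on the sphere.

All distances are great-circle distances in kilometres on a sphere of
radius ``EARTH_RADIUS_KM``.  Grids are cell-center registered, latitude
ascending, longitude equally spaced and periodic in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Grid:
    """A regular lat-lon grid.

    Parameters
    ----------
    lat_centers : array of float
        Cell-center latitudes in degrees north, strictly increasing,
        strictly inside (-90, 90) except possibly the poles themselves.
    lon_centers : array of float
        Cell-center longitudes in degrees east, equally spaced; treated
        as periodic with wraparound.
    earth_radius : float
        Sphere radius in km.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    earth_radius: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", np.mod(lon, 360.0))
        if lat.ndim != 1 or lon.ndim != 1:
            raise ValueError("lat_centers and lon_centers must be 1-D")
        if np.any(np.diff(lat) <= 0):
            raise ValueError("lat_centers must be strictly increasing")
        if np.any(lat < -90.0) or np.any(lat > 90.0):
            raise ValueError("latitudes must lie in [-90, 90]")
        dlon = np.diff(np.unwrap(np.deg2rad(lon)))
        if lon.size > 1 and not np.allclose(dlon, dlon[0], rtol=1e-6, atol=1e-9):
            raise ValueError("lon_centers must be equally spaced")

    @property
    def nlat(self) -> int:
        return self.lat_centers.size

    @property
    def nlon(self) -> int:
        return self.lon_centers.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def dlat_deg(self) -> float:
        """Meridional grid spacing in degrees (uniform spacing assumed)."""
        return float(np.mean(np.diff(self.lat_centers)))

    @property
    def dlon_deg(self) -> float:
        """Zonal grid spacing in degrees."""
        if self.nlon < 2:
            raise ValueError("need at least 2 longitudes for a spacing")
        d = np.diff(np.unwrap(np.deg2rad(self.lon_centers)))
        return float(np.rad2deg(np.mean(d)))

    def dy_km(self) -> float:
        """Meridional spacing R*dphi in km (constant on a regular grid)."""
        return self.earth_radius * np.deg2rad(self.dlat_deg)

    def dx_km(self) -> np.ndarray:
        """Zonal spacing R*cos(phi_j)*dlambda in km, per latitude row."""
        coslat = np.cos(np.deg2rad(self.lat_centers))
        return self.earth_radius * np.abs(coslat) * np.deg2rad(self.dlon_deg)

    def matches(self, other: "Grid", atol: float = 1e-8) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat_centers, other.lat_centers, atol=atol)
            and np.allclose(self.lon_centers, other.lon_centers, atol=atol)
        )


def regular_grid(nlat: int, nlon: int, earth_radius: float = EARTH_RADIUS_KM) -> Grid:
    """Equally spaced global grid with cell centers offset from the poles.

    Latitude centers sit at the midpoints of nlat equal bands, so no center
    falls exactly on a pole and cos(lat) > 0 everywhere.
    """
    dlat = 180.0 / nlat
    lat = -90.0 + dlat * (np.arange(nlat) + 0.5)
    lon = 360.0 / nlon * np.arange(nlon)
    return Grid(lat, lon, earth_radius)


def cell_area_weights(grid: Grid, normalized: bool = False) -> np.ndarray:
    """Per-cell spherical area weights, shape (nlat, nlon).

    Unnormalized weights are true cell areas in km^2 computed from the
    exact band integral R^2 * dlambda * (sin(phi_top) - sin(phi_bot));
    over a full global grid they sum to 4*pi*R^2.  With ``normalized``
    the weights sum to 1.
    """
    lat = grid.lat_centers
    # band edges from midpoints; clamp outer edges to the poles for global grids
    edges = np.empty(lat.size + 1)
    edges[1:-1] = 0.5 * (lat[:-1] + lat[1:])
    edges[0] = max(-90.0, lat[0] - 0.5 * grid.dlat_deg)
    edges[-1] = min(90.0, lat[-1] + 0.5 * grid.dlat_deg)
    band = np.sin(np.deg2rad(edges[1:])) - np.sin(np.deg2rad(edges[:-1]))
    dlam = np.deg2rad(grid.dlon_deg if grid.nlon > 1 else 360.0)
    areas = grid.earth_radius**2 * np.abs(dlam) * band
    w = np.repeat(areas[:, None], grid.nlon, axis=1)
    if normalized:
        w = w / w.sum()
    return w
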