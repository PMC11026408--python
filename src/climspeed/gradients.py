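"""Temporal trends and spatial gradients of gridded temperature.

These are the two ingredients of the climate velocity: the per-cell
ordinary-least-squares trend of annual temperature (K/yr) and the
spatial gradient of the window-mean temperature field (K/km), the
latter from a 3x3 neighborhood-slope (Sobel) stencil normalized so it
is exact on locally linear fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .io import TemperatureCube

DEFAULT_GRADIENT_FLOOR = 1e-4  # K/km; keeps Eq.-of-motion speeds finite where grad -> 0


@dataclass
class TrendField:
    """Per-cell OLS slope of annual temperature vs. year, K/yr."""

    grid: Grid
    slope: np.ndarray  # K/yr, (nlat, nlon)
    window: tuple[int, int]  # (start_year, end_year), inclusive
    member_id: str = "member_0"

    @property
    def window_years(self) -> int:
        return self.window[1] - self.window[0] + 1


@dataclass
class GradientField:
    """Spatial gradient of a 2-D temperature field, K/km.

    g_east / g_north are the eastward and northward components;
    ``magnitude`` is their Euclidean norm, possibly raised to a floor.
    ``edge_rows`` flags cells in the first/last latitude rows, where the
    stencil used replicate padding; ``floored`` flags cells whose
    magnitude was clipped up to the floor.
    """

    grid: Grid
    g_east: np.ndarray
    g_north: np.ndarray
    magnitude: np.ndarray
    edge_rows: np.ndarray = field(default=None)  # bool (nlat, nlon)
    floored: np.ndarray = field(default=None)  # bool (nlat, nlon)
    floor_eps: float | None = None

    def __post_init__(self) -> None:
        if self.edge_rows is None:
            self.edge_rows = np.zeros(self.grid.shape, dtype=bool)
        if self.floored is None:
            self.floored = np.zeros(self.grid.shape, dtype=bool)

    @property
    def n_floored(self) -> int:
        return int(self.floored.sum())


def temporal_trend(cube: TemperatureCube, window: tuple[int, int]) -> TrendField:
    """OLS slope of annual temperature against calendar year, per cell.

    Years are centered on the window mean before regression for
    numerical conditioning; the intercept is discarded.
    """
    start, end = int(window[0]), int(window[1])
    sub = cube.select_years(start, end)
    t = sub.years.astype(float)
    tc = t - t.mean()
    denom = np.sum(tc**2)
    if denom == 0:
        raise ValueError("window must contain at least 2 years")
    # slope = sum_t tc * (T - Tbar) / sum tc^2 ; the Tbar term drops since sum tc = 0
    slope = np.tensordot(tc, sub.values, axes=(0, 0)) / denom
    return TrendField(cube.grid, slope, (start, end), cube.member_id)


def period_mean(cube: TemperatureCube, window: tuple[int, int]) -> np.ndarray:
    """Arithmetic mean temperature over the window years, per cell (K)."""
    sub = cube.select_years(int(window[0]), int(window[1]))
    return sub.values.mean(axis=0)


def spatial_gradient(meanfield: np.ndarray, grid: Grid) -> GradientField:
    """3x3 neighborhood-slope (Sobel) gradient of a 2-D field, K/km.

    g_east(j,i) = [(T_NE + 2 T_E + T_SE) - (T_NW + 2 T_W + T_SW)] / (8 dx_j)
    with the analogous stencil over rows for g_north; dx_j uses
    cos(lat) at the cell's own latitude.  Longitude wraps periodically;
    the first/last latitude rows use replicate padding and are flagged.
    """
    f = np.asarray(meanfield, dtype=float)
    if f.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    nlat, nlon = grid.shape
    if nlat < 3 or nlon < 3:
        raise ValueError("grid too small for a 3x3 stencil (need nlat,nlon >= 3)")

    # pad: replicate in latitude, wrap in longitude
    p = np.pad(f, ((1, 1), (0, 0)), mode="edge")
    p = np.concatenate([p[:, -1:], p, p[:, :1]], axis=1)

    c = p[1:-1, 1:-1]  # noqa: F841  (kept for readability of the stencil)
    n, s = p[2:, 1:-1], p[:-2, 1:-1]
    e, w = p[1:-1, 2:], p[1:-1, :-2]
    ne, nw = p[2:, 2:], p[2:, :-2]
    se, sw = p[:-2, 2:], p[:-2, :-2]

    dx = grid.dx_km()[:, None]
    dy = grid.dy_km()
    with np.errstate(divide="ignore", invalid="ignore"):
        g_east = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8.0 * dx)
    g_north = ((ne + 2 * n + nw) - (se + 2 * s + sw)) / (8.0 * dy)
    g_east = np.where(np.isfinite(g_east), g_east, 0.0)  # exact pole rows: dx = 0

    edge = np.zeros(grid.shape, dtype=bool)
    edge[0, :] = True
    edge[-1, :] = True
    mag = np.hypot(g_east, g_north)
    return GradientField(grid, g_east, g_north, mag, edge_rows=edge)


def apply_gradient_floor(
    grad: GradientField, floor_eps: float = DEFAULT_GRADIENT_FLOOR
) -> GradientField:
    """Clip the gradient magnitude up to ``floor_eps`` (K/km).

    The climate-velocity ratio is singular where the spatial gradient
    vanishes; the floor bounds speeds at |trend|/floor_eps.  Component
    direction is unchanged; floored cells are flagged and counted.
    """
    if floor_eps <= 0:
        raise ValueError("floor_eps must be positive")
    floored = grad.magnitude < floor_eps
    mag = np.maximum(grad.magnitude, floor_eps)
    return GradientField(
        grad.grid,
        grad.g_east,
        grad.g_north,
        mag,
        edge_rows=grad.edge_rows,
        floored=floored,
        floor_eps=floor_eps,
    )
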