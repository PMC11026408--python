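"""Signed climate speed (the climate-velocity magnitude) per member,
and ensemble summaries.

The climate velocity of temperature is the ratio of the temporal trend
dT/dt (K/yr) to the spatial gradient |grad T| (K/km); its magnitude,
the climate speed, is in km/yr.  A sign is imposed from the local
trend: positive speeds accompany warming, negative speeds cooling.
The ensemble mean is always taken after the per-member speed
calculation, never on averaged temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid, cell_area_weights
from .gradients import GradientField, TrendField, temporal_trend
from .io import TemperatureCube


@dataclass
class SpeedField:
    """Per-cell signed climate speed for one ensemble member.

    speed_signed : km/yr, sign = sign of the local temperature trend.
    direction : degrees clockwise from north of the displacement an
        organism must make to hold its temperature — down the spatial
        gradient under warming, up it under cooling.  NaN where the
        gradient was floored (direction undefined).
    valid : cells where both the stencil was interior and the gradient
        was not floored; area statistics restrict to these by default.
    """

    grid: Grid
    speed_signed: np.ndarray
    direction: np.ndarray
    member_id: str
    window: tuple[int, int]
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.speed_signed)


@dataclass
class EnsembleSpeed:
    """Member speed fields plus their per-cell signed mean."""

    members: list[SpeedField]
    ensemble_mean: np.ndarray
    n_members: int

    @property
    def grid(self) -> Grid:
        return self.members[0].grid

    @property
    def window(self) -> tuple[int, int]:
        return self.members[0].window

    @property
    def valid(self) -> np.ndarray:
        v = self.members[0].valid.copy()
        for m in self.members[1:]:
            v &= m.valid
        return v


def climate_speed(trend: TrendField, grad: GradientField) -> SpeedField:
    """Combine a trend field and a (floored) gradient field into the
    signed climate-speed field, km/yr.

    |speed| = |slope| / |grad|; sign(speed) = sign(slope); zero trend
    gives exactly zero signed speed.  Unit pipeline is fixed:
    K/yr divided by K/km gives km/yr.
    """
    if not trend.grid.matches(grad.grid):
        raise ValueError("trend and gradient grids do not match")
    mag = np.abs(trend.slope) / grad.magnitude
    signed = np.sign(trend.slope) * mag

    # displacement direction: down-gradient for warming trends
    ux = -np.sign(trend.slope) * grad.g_east
    uy = -np.sign(trend.slope) * grad.g_north
    with np.errstate(invalid="ignore"):
        direction = np.rad2deg(np.arctan2(ux, uy)) % 360.0
    direction = np.where(grad.floored | (trend.slope == 0), np.nan, direction)

    valid = ~(grad.edge_rows | grad.floored)
    return SpeedField(trend.grid, signed, direction, trend.member_id, trend.window, valid)


def ensemble_mean_speed(members: list[SpeedField]) -> EnsembleSpeed:
    """Per-cell arithmetic mean of the members' *signed* speeds.

    Warming and cooling members cancel in this mean by construction;
    magnitude statistics downstream operate on the per-member fields.
    """
    if len(members) == 0:
        raise ValueError("need at least one member")
    g = members[0].grid
    win = members[0].window
    for m in members[1:]:
        if not m.grid.matches(g) or m.window != win:
            raise ValueError("members differ in grid or window")
    mean = np.mean([m.speed_signed for m in members], axis=0)
    return EnsembleSpeed(list(members), mean, len(members))


def speeds_from_cubes(
    cubes: list[TemperatureCube],
    window: tuple[int, int],
    floor_eps: float | None = None,
) -> EnsembleSpeed:
    """Convenience pipeline: trend + window-mean gradient -> speeds for
    every member, then the ensemble mean of signed speeds."""
    from .gradients import DEFAULT_GRADIENT_FLOOR, apply_gradient_floor, period_mean, spatial_gradient

    eps = DEFAULT_GRADIENT_FLOOR if floor_eps is None else floor_eps
    fields = []
    for cube in cubes:
        tr = temporal_trend(cube, window)
        gr = apply_gradient_floor(spatial_gradient(period_mean(cube, window), cube.grid), eps)
        fields.append(climate_speed(tr, gr))
    return ensemble_mean_speed(fields)


def global_mean_series(cube: TemperatureCube) -> np.ndarray:
    """cos-lat area-weighted global annual mean temperature series (K)."""
    w = cell_area_weights(cube.grid, normalized=True)
    return np.tensordot(cube.values, w, axes=([1, 2], [0, 1]))


def global_mean_temperature_rate(cube: TemperatureCube, window: tuple[int, int]) -> float:
    """OLS slope of the area-weighted global annual mean over the window,
    in degrees C per year (identical to K/yr)."""
    sub = cube.select_years(int(window[0]), int(window[1]))
    series = global_mean_series(sub)
    t = sub.years.astype(float)
    tc = t - t.mean()
    return float(np.sum(tc * (series - series.mean())) / np.sum(tc**2))
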