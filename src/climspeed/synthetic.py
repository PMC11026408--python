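"""Synthetic gridded-temperature ensembles with known ground truth.

Each member is a deterministic climatology + per-cell linear trend,
plus AR(1) interannual noise that is independent across members, plus
optional short-lived eruption cooling spikes:

    T_m(t,j,i) = base + Gy*d_north(j) + Gx*d_east(j,i)
                 + trend(j,i)*(t - t0) + eta_m(t,j,i) + sum_k eruption_k(t)

Because the climatology is analytic, the trend field, spatial-gradient
field and implied climate speed are known in closed form
(:class:`SyntheticTruth`), giving every downstream stage an exact
oracle without any model output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .grid import Grid, regular_grid
from .io import SurfaceMask, TemperatureCube


@dataclass
class Eruption:
    """A brief volcanic cooling spike: -amplitude * exp(-(t-year)/efold)
    for t >= year, zero before."""

    year: int
    amplitude_k: float
    efold_years: float = 2.0


@dataclass
class SyntheticConfig:
    """Generator settings.

    The defaults mirror a 10-member, 20-year scenario ensemble on a
    coarse global grid: climatological meridional gradient 0.01 K/km
    (a planetary-scale pole-to-equator contrast), no zonal gradient,
    AR(1) interannual noise with 0.25 K innovations and lag-1
    autocorrelation 0.5 — interannual variance and persistence typical
    of annual-mean 2-m temperature at grid scale.
    """

    nlat: int = 48
    nlon: int = 72
    base_temp_k: float = 288.0
    meridional_gradient: float = 0.01  # K/km, climatological; >= 0 poleward cooling
    zonal_gradient: float = 0.0  # K/km
    trend: float | np.ndarray = 0.0  # K/yr, scalar or (nlat, nlon) map
    noise_sigma: float = 0.25  # K, AR(1) innovation scale
    noise_rho: float = 0.5  # lag-1 autocorrelation, in [0, 1)
    n_members: int = 10
    n_years: int = 20
    start_year: int = 2035
    seed: int = 0
    eruptions: Sequence[Eruption] = dc_field(default_factory=tuple)
    noise_smoothing_cells: float = 0.0  # >0: Gaussian spatial correlation length, in cells
    land_band: tuple[float, float] | None = (-60.0, 75.0)  # lat band marked as land
    land_lon_band: tuple[float, float] | None = (0.0, 120.0)  # lon range of the land rectangle

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rho < 1.0):
            raise ValueError("noise_rho must be in [0, 1)")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.nlat < 3 or self.nlon < 3:
            raise ValueError("grid too small: need nlat, nlon >= 3 for a 3x3 stencil")
        if not np.all(np.isfinite([self.meridional_gradient, self.zonal_gradient])):
            raise ValueError("gradients must be finite")


@dataclass
class SyntheticTruth:
    """Closed-form per-cell truth implied by the generating config."""

    grid: Grid
    trend: np.ndarray  # K/yr
    g_east: np.ndarray  # K/km
    g_north: np.ndarray  # K/km
    speed: np.ndarray  # km/yr, |trend| / |grad| (inf where grad = 0)

    @property
    def gradient_magnitude(self) -> np.ndarray:
        return np.hypot(self.g_east, self.g_north)


def eruption_series(
    year: int, amplitude_k: float, efold_years: float, years: np.ndarray
) -> np.ndarray:
    """Additive global-mean cooling from one eruption, per year."""
    if efold_years <= 0:
        raise ValueError("efold_years must be positive")
    years = np.asarray(years, dtype=float)
    dt = years - year
    return np.where(dt >= 0, -amplitude_k * np.exp(-dt / efold_years), 0.0)


def _climatology(cfg: SyntheticConfig, grid: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic climatological field and its analytic gradient.

    Distances are measured from the domain's south-west corner along
    great circles at the cell's own latitude, so the designed gradients
    are exact in K/km on the sphere:
        d_north(j)   = R * (phi_j - phi_0)
        d_east(j,i)  = R * cos(phi_j) * (lam_i - lam_0)
    The zonal term makes d_east latitude-dependent, which feeds a
    -Gx * (lam - lam_0) * sin(phi) correction into the true northward
    gradient; the truth accounts for it.
    """
    R = grid.earth_radius
    phi = np.deg2rad(grid.lat_centers)[:, None]
    lam = np.unwrap(np.deg2rad(grid.lon_centers))[None, :]
    d_north = R * (phi - phi[0, 0])
    d_east = R * np.cos(phi) * (lam - lam[0, 0])

    clim = cfg.base_temp_k + cfg.meridional_gradient * d_north + cfg.zonal_gradient * d_east
    g_east = np.full(grid.shape, cfg.zonal_gradient)
    g_north = cfg.meridional_gradient - cfg.zonal_gradient * (lam - lam[0, 0]) * np.sin(phi)
    g_north = np.broadcast_to(g_north, grid.shape).copy()
    return clim, g_east, g_north


def _ar1_noise(
    rng: np.random.Generator, cfg: SyntheticConfig, shape: tuple[int, int, int]
) -> np.ndarray:
    """AR(1)-in-time noise, initialized from the stationary distribution."""
    n_years, nlat, nlon = shape
    sigma, rho = cfg.noise_sigma, cfg.noise_rho
    eta = np.empty(shape)
    innov = rng.standard_normal(shape) * sigma
    if cfg.noise_smoothing_cells > 0:
        from scipy.ndimage import gaussian_filter

        s = cfg.noise_smoothing_cells
        for t in range(n_years):  # wrap in lon, reflect in lat; rescale to keep sigma
            innov[t] = gaussian_filter(innov[t], sigma=s, mode=("nearest", "wrap"))
        innov *= np.sqrt(4 * np.pi * s**2)  # approximate variance restoration
    eta[0] = innov[0] / np.sqrt(1.0 - rho**2) if rho > 0 else innov[0]
    for t in range(1, n_years):
        eta[t] = rho * eta[t - 1] + innov[t]
    return eta


def generate_ensemble(
    cfg: SyntheticConfig,
) -> tuple[list[TemperatureCube], SurfaceMask, SyntheticTruth]:
    """Generate an ensemble of temperature cubes plus mask and truth.

    Identical seeds give bit-identical output; member noise streams are
    independent children of the master seed.
    """
    grid = regular_grid(cfg.nlat, cfg.nlon)
    clim, g_east, g_north = _climatology(cfg, grid)

    trend = np.asarray(cfg.trend, dtype=float)
    if trend.ndim == 0:
        trend = np.full(grid.shape, float(trend))
    if trend.shape != grid.shape:
        raise ValueError("trend map shape does not match grid")

    years = cfg.start_year + np.arange(cfg.n_years)
    t_rel = (years - years[0]).astype(float)

    forcing = np.zeros(cfg.n_years)
    for er in cfg.eruptions:
        forcing += eruption_series(er.year, er.amplitude_k, er.efold_years, years)

    deterministic = (
        clim[None, :, :]
        + trend[None, :, :] * t_rel[:, None, None]
        + forcing[:, None, None]
    )

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_members)
    cubes = []
    for m, ss in enumerate(streams):
        if cfg.noise_sigma > 0:
            eta = _ar1_noise(np.random.default_rng(ss), cfg, (cfg.n_years, cfg.nlat, cfg.nlon))
        else:
            eta = 0.0
        cubes.append(
            TemperatureCube(grid, years, deterministic + eta, member_id=f"member_{m}")
        )

    if cfg.land_band is not None:
        lo, hi = cfg.land_band
        in_lat = (grid.lat_centers >= lo) & (grid.lat_centers <= hi)
        frac = np.repeat(in_lat.astype(float)[:, None], cfg.nlon, axis=1)
        if cfg.land_lon_band is not None:
            llo, lhi = np.mod(cfg.land_lon_band[0], 360.0), np.mod(cfg.land_lon_band[1], 360.0)
            lons = grid.lon_centers
            in_lon = (lons >= llo) & (lons <= lhi) if llo <= lhi else (lons >= llo) | (lons <= lhi)
            frac *= in_lon[None, :].astype(float)
    else:
        frac = np.zeros(grid.shape)
    mask = SurfaceMask(grid, frac)

    gmag = np.hypot(g_east, g_north)
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(gmag > 0, np.abs(trend) / gmag, np.inf)
    truth = SyntheticTruth(grid, trend, g_east, g_north, speed)
    return cubes, mask, truth
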