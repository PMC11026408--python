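"""Risk statistics from climate-speed fields.

Area-weighted threshold-exposure fractions, weighted medians of the
climate speed over land/ocean/regions, regional means, the ensemble
sign-agreement (binomial) robustness test, and multi-period speed
distributions.  All area statistics use cos-lat (true spherical) cell
weights — unweighted cell counts on a lat-lon grid would overrepresent
the poles — and restrict to each field's valid cells (interior stencil
rows, unfloored gradients) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .grid import Grid, cell_area_weights
from .gradients import TrendField
from .io import SurfaceMask, TemperatureCube
from .velocity import EnsembleSpeed, SpeedField

#: Default exceedance thresholds, km/yr: ~2 mean terrestrial dispersal,
#: ~7 mean marine dispersal, 10 extreme risk (exceeds adaptable families),
#: 5 and 50 as intermediate/extreme reference values.
DEFAULT_THRESHOLDS = (2.0, 5.0, 7.0, 10.0, 50.0)


@dataclass
class RegionBox:
    """A named lat/lon box; lon bounds may wrap across 0/360."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def cell_mask(self, grid: Grid) -> np.ndarray:
        in_lat = (grid.lat_centers >= self.lat_min) & (grid.lat_centers <= self.lat_max)
        lo, hi = np.mod(self.lon_min, 360.0), np.mod(self.lon_max, 360.0)
        lons = grid.lon_centers
        in_lon = (lons >= lo) & (lons <= hi) if lo <= hi else (lons >= lo) | (lons <= hi)
        out = in_lat[:, None] & in_lon[None, :]
        if not out.any():
            raise ValueError(f"region {self.name!r} does not intersect the grid")
        return out


@dataclass
class ExposureSummary:
    """Exposure fractions and weighted medians for one domain/window."""

    domain: str
    window: tuple[int, int]
    thresholds: tuple[float, ...]
    #: per member: {member_id: {threshold: percent}}
    member_fractions: dict[str, dict[float, float]]
    #: percent of area exceeding each threshold in the |ensemble-mean signed speed| field
    ensemble_field_fractions: dict[float, float]
    #: ensemble mean of the member-wise fractions, per threshold
    mean_fractions: dict[float, float]
    member_medians: dict[str, float]  # weighted median |speed| per member
    member_medians_signed: dict[str, float]
    ensemble_median: float  # weighted median of the |ensemble-mean| field
    mean_of_member_medians: float

    _COLUMNS = (
        "domain",
        "window_start",
        "window_end",
        "member",
        "threshold_km_yr",
        "fraction_pct",
        "median_abs_km_yr",
        "median_signed_km_yr",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid in sorted(self.member_fractions):
            for thr in self.thresholds:
                rows.append(
                    {
                        "domain": self.domain,
                        "window_start": self.window[0],
                        "window_end": self.window[1],
                        "member": mid,
                        "threshold_km_yr": thr,
                        "fraction_pct": self.member_fractions[mid][thr],
                        "median_abs_km_yr": self.member_medians[mid],
                        "median_signed_km_yr": self.member_medians_signed[mid],
                    }
                )
        for thr in self.thresholds:
            rows.append(
                {
                    "domain": self.domain,
                    "window_start": self.window[0],
                    "window_end": self.window[1],
                    "member": "ensemble",
                    "threshold_km_yr": thr,
                    "fraction_pct": self.mean_fractions[thr],
                    "median_abs_km_yr": self.mean_of_member_medians,
                    "median_signed_km_yr": self.ensemble_median,
                }
            )
        return pd.DataFrame(rows, columns=list(self._COLUMNS))


@dataclass
class RobustnessMap:
    """Per-cell ensemble sign agreement under a two-sided binomial test."""

    grid: Grid
    agree_count: np.ndarray  # members sharing the majority trend sign
    p_value: np.ndarray
    robust: np.ndarray  # p < alpha
    n_members: int
    alpha: float = 0.1


def _weights_for_domain(
    grid: Grid,
    mask: SurfaceMask | None,
    domain: str | RegionBox,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    w = cell_area_weights(grid)
    if isinstance(domain, RegionBox):
        cells = domain.cell_mask(grid)
        if mask is not None:
            cells = cells & mask.domain_mask("land")  # regions default to land cells
    else:
        cells = (
            mask.domain_mask(domain)
            if mask is not None
            else np.ones(grid.shape, dtype=bool)
        )
    if valid is not None:
        cells = cells & valid
    w = np.where(cells, w, 0.0)
    if w.sum() <= 0:
        raise ValueError("empty domain after masking")
    return w / w.sum()


def area_fraction_exceeding(
    speed: np.ndarray,
    grid: Grid,
    mask: SurfaceMask | None,
    domain: str | RegionBox,
    threshold: float,
    valid: np.ndarray | None = None,
) -> float:
    """Percent of domain area where |speed| strictly exceeds threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    w = _weights_for_domain(grid, mask, domain, valid)
    return float(100.0 * w[np.abs(speed) > threshold].sum())


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median: smallest value whose cumulative weight reaches
    50%, with linear interpolation when a value's cumulative weight hits
    exactly 50% (the midpoint of the straddling pair)."""
    v = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    keep = w > 0
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise ValueError("empty domain")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cum, 0.5, side="left"))
    if np.isclose(cum[idx], 0.5, rtol=0.0, atol=1e-12) and idx + 1 < v.size:
        return float(0.5 * (v[idx] + v[idx + 1]))
    return float(v[idx])


def weighted_median_speed(
    speed: np.ndarray,
    grid: Grid,
    mask: SurfaceMask | None,
    domain: str | RegionBox,
    use_magnitude: bool = True,
    valid: np.ndarray | None = None,
) -> float:
    """cos-lat weighted median of |speed| (or signed speed) over a domain."""
    w = _weights_for_domain(grid, mask, domain, valid)
    vals = np.abs(speed) if use_magnitude else speed
    return weighted_median(vals, w)


def region_mean_speed(
    ens: EnsembleSpeed,
    region: RegionBox,
    mask: SurfaceMask | None = None,
    use_magnitude: bool = True,
) -> tuple[float, float]:
    """cos-lat weighted mean of the ensemble-mean speed over a region.

    Returns (mean speed km/yr, implied displacement km over the window),
    displacement = mean speed x window length in years: the distance an
    organism must track isotherms over the analysis period.
    """
    w = _weights_for_domain(ens.grid, mask, region, ens.valid)
    vals = np.abs(ens.ensemble_mean) if use_magnitude else ens.ensemble_mean
    mean = float(np.sum(w * vals))
    nyears = ens.window[1] - ens.window[0] + 1
    return mean, mean * nyears


def robustness_test(
    member_trends: list[TrendField], alpha: float = 0.1, two_sided: bool = True
) -> RobustnessMap:
    """Ensemble sign-agreement test per cell.

    k = number of members whose trend sign matches the majority sign
    (exact zero trends count as disagreeing — conservative).  Under the
    null each member's sign is a fair coin: p = P(X >= k) + P(X <= n-k)
    for X ~ Binomial(n, 1/2) (clipped to 1 on an even split), or the
    single upper tail when ``two_sided`` is off.  Cells with p < alpha
    are flagged robust: the forced response dominates internal noise.
    """
    n = len(member_trends)
    if n < 2:
        raise ValueError("robustness test needs at least 2 members")
    g = member_trends[0].grid
    signs = np.stack([np.sign(tf.slope) for tf in member_trends])
    pos = (signs > 0).sum(axis=0)
    neg = (signs < 0).sum(axis=0)
    k = np.maximum(pos, neg)
    p = binom.sf(k - 1, n, 0.5)  # P(X >= k)
    if two_sided:
        p = p + binom.cdf(n - k, n, 0.5)
    p = np.minimum(p, 1.0)
    return RobustnessMap(g, k, p, p < alpha, n, alpha)


def summarize_exposure(
    ens: EnsembleSpeed,
    mask: SurfaceMask | None,
    domain: str | RegionBox,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> ExposureSummary:
    """Full exposure summary for one domain: per-member and ensemble
    fractions at each threshold plus weighted medians."""
    thresholds = tuple(float(t) for t in thresholds)
    valid = ens.valid
    g = ens.grid
    member_fractions: dict[str, dict[float, float]] = {}
    member_medians: dict[str, float] = {}
    member_medians_signed: dict[str, float] = {}
    for m in ens.members:
        member_fractions[m.member_id] = {
            t: area_fraction_exceeding(m.speed_signed, g, mask, domain, t, valid)
            for t in thresholds
        }
        member_medians[m.member_id] = weighted_median_speed(
            m.speed_signed, g, mask, domain, True, valid
        )
        member_medians_signed[m.member_id] = weighted_median_speed(
            m.speed_signed, g, mask, domain, False, valid
        )
    ens_field_fracs = {
        t: area_fraction_exceeding(ens.ensemble_mean, g, mask, domain, t, valid)
        for t in thresholds
    }
    mean_fracs = {
        t: float(np.mean([member_fractions[m][t] for m in member_fractions]))
        for t in thresholds
    }
    return ExposureSummary(
        domain=domain.name if isinstance(domain, RegionBox) else domain,
        window=ens.window,
        thresholds=thresholds,
        member_fractions=member_fractions,
        ensemble_field_fractions=ens_field_fracs,
        mean_fractions=mean_fracs,
        member_medians=member_medians,
        member_medians_signed=member_medians_signed,
        ensemble_median=weighted_median_speed(ens.ensemble_mean, g, mask, domain, True, valid),
        mean_of_member_medians=float(np.mean(list(member_medians.values()))),
    )


def speed_distribution_over_periods(
    cube: TemperatureCube,
    periods: list[tuple[int, int]],
    mask: SurfaceMask | None,
    domain: str | RegionBox,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    floor_eps: float | None = None,
) -> tuple[list[tuple[tuple[int, int], ExposureSummary]], dict[float, float]]:
    """Single-member speed statistics over a list of analysis periods.

    Returns per-period summaries plus the across-period maximum
    exposure fraction at each threshold (the natural-variability
    envelope a scenario is compared against).
    """
    from .velocity import speeds_from_cubes

    out = []
    for (start, end) in periods:
        ens = speeds_from_cubes([cube], (start, end), floor_eps)
        out.append(((start, end), summarize_exposure(ens, mask, domain, thresholds)))
    max_fracs = {
        float(t): max(summ.mean_fractions[float(t)] for _, summ in out) for t in thresholds
    }
    return out, max_fracs
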