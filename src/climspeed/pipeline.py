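"""End-to-end scenario orchestration.

Selects analysis windows (excluding periods near large volcanic
eruptions), runs the full trend -> gradient -> speed -> exposure chain
for one scenario ensemble, and assembles the multi-scenario risk
plane: global temperature-change rate (x) against percent of global
area exposed to climate speeds beyond a threshold (y), with the
natural-variability maximum as a reference line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exposure import (
    DEFAULT_THRESHOLDS,
    ExposureSummary,
    RegionBox,
    RobustnessMap,
    robustness_test,
    summarize_exposure,
)
from .gradients import DEFAULT_GRADIENT_FLOOR, apply_gradient_floor, period_mean, spatial_gradient, temporal_trend
from .io import SurfaceMask, TemperatureCube, read_mask, read_temperature, write_summary
from .velocity import climate_speed, ensemble_mean_speed, global_mean_temperature_rate


@dataclass(frozen=True)
class AnalysisPeriod:
    """An inclusive [start, end] analysis window, at least 10 years long
    (climate speeds are not meaningful on shorter horizons)."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError(
                f"window {self.start_year}-{self.end_year} is shorter than 10 years"
            )

    @property
    def window(self) -> int:
        return self.end_year - self.start_year + 1

    def as_tuple(self) -> tuple[int, int]:
        return (self.start_year, self.end_year)


@dataclass(frozen=True)
class EruptionRecord:
    """One volcanic eruption: calendar year and stratospheric sulfate mass."""

    year: int
    sulfate_tg: float

    def __post_init__(self) -> None:
        if self.sulfate_tg < 0:
            raise ValueError("sulfate mass must be >= 0")


@dataclass
class RiskPoint:
    """One scenario's coordinates in the risk plane."""

    scenario: str
    rate_mean: float  # global mean temperature-change rate, degC/yr
    rate_min: float
    rate_max: float
    exposed_mean: float  # % global area with |speed| > threshold
    exposed_min: float
    exposed_max: float
    threshold_km_yr: float = 10.0

    def __post_init__(self) -> None:
        if not (self.rate_min <= self.rate_mean <= self.rate_max):
            raise ValueError("rate spread must bracket the mean")
        if not (self.exposed_min <= self.exposed_mean <= self.exposed_max):
            raise ValueError("exposure spread must bracket the mean")


@dataclass
class ScenarioConfig:
    """Everything needed to run one scenario deterministically."""

    label: str
    period: AnalysisPeriod
    input_files: Sequence[str] = dc_field(default_factory=tuple)  # one per member
    mask_file: str | None = None
    varname: str = "t2m"
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    gradient_floor: float = DEFAULT_GRADIENT_FLOOR
    regions: Sequence[RegionBox] = dc_field(default_factory=tuple)
    risk_threshold: float = 10.0
    out_dir: str | None = None
    seed: int = 0


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    summaries: dict[str, ExposureSummary]  # keyed by domain name
    risk_point: RiskPoint
    robustness: RobustnessMap
    ensemble: "object"  # EnsembleSpeed
    manifest: dict


def select_clean_periods(
    record: Sequence[EruptionRecord],
    span: tuple[int, int],
    window: int,
    buffer_years: int = 5,
    mass_threshold_tg: float = 10.0,
    mode: str = "non_overlapping",
    listed: Sequence[tuple[int, int]] | None = None,
) -> list[AnalysisPeriod]:
    """Select analysis windows unaffected by large volcanic eruptions.

    A window [start, end] conflicts with an eruption of mass >=
    ``mass_threshold_tg`` when the eruption year lies in
    [start - buffer, end + buffer] (inclusive: "within 5 years").

    non_overlapping mode tiles candidate windows from the span start,
    advancing by the window length, and drops conflicted ones.  listed
    mode validates a user-provided window list against the record and
    warns about (and drops) any conflicted entries, surfacing
    discrepancies instead of silently passing them through.
    """
    first, last = span
    if last - first + 1 <= window:
        raise ValueError("span must be longer than the window")
    big = [er.year for er in record if er.sulfate_tg >= mass_threshold_tg]

    def conflict(start: int, end: int) -> list[int]:
        return [y for y in big if start - buffer_years <= y <= end + buffer_years]

    periods: list[AnalysisPeriod] = []
    if mode == "non_overlapping":
        start = first
        while start + window - 1 <= last:
            end = start + window - 1
            if not conflict(start, end):
                periods.append(AnalysisPeriod(start, end))
            start += window
    elif mode == "listed":
        if listed is None:
            raise ValueError("listed mode requires a window list")
        for (start, end) in listed:
            if end - start + 1 != window:
                raise ValueError(f"listed window {start}-{end} is not {window} years long")
            bad = conflict(start, end)
            if bad:
                warnings.warn(
                    f"window {start}-{end} conflicts with eruption(s) in year(s) {bad} "
                    f"(>= {mass_threshold_tg} Tg within {buffer_years} yr); dropped",
                    stacklevel=2,
                )
            else:
                periods.append(AnalysisPeriod(start, end))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not periods:
        raise ValueError("no valid analysis periods in span")
    return periods


def read_eruption_csv(path: str | Path) -> list[EruptionRecord]:
    """Read an eruption record from CSV with columns (year, sulfate_tg)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    ycol = cols.get("year")
    mcol = cols.get("sulfate_tg") or cols.get("tg") or cols.get("mass_tg")
    if ycol is None or mcol is None:
        raise ValueError("eruption CSV needs 'year' and 'sulfate_tg' (or 'tg') columns")
    return [EruptionRecord(int(r[ycol]), float(r[mcol])) for _, r in df.iterrows()]


def _manifest_config(config: ScenarioConfig) -> dict:
    # out_dir is a delivery detail, not part of the scientific configuration:
    # reruns into different directories must produce identical manifests
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)
    return d


def _config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(_manifest_config(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_scenario(
    config: ScenarioConfig,
    cubes: Sequence[TemperatureCube] | None = None,
    mask: SurfaceMask | None = None,
) -> ScenarioResult:
    """Run the full pipeline for one scenario ensemble.

    Members may be passed in memory (``cubes``/``mask``) or read from
    ``config.input_files``/``config.mask_file``.  Deterministic given
    inputs and config; a manifest with the resolved config, its hash
    and floored-cell counts is produced (and written alongside outputs
    when ``config.out_dir`` is set).
    """
    try:
        if cubes is None:
            if not config.input_files:
                raise ValueError("no input cubes or files provided")
            cubes = [read_temperature(p, config.varname) for p in config.input_files]
        if mask is None and config.mask_file:
            mask = read_mask(config.mask_file)

        window = config.period.as_tuple()
        grid = cubes[0].grid
        for c in cubes[1:]:
            if not c.grid.matches(grid):
                raise ValueError("ensemble members are on inconsistent grids")

        trends, speeds, floored_counts = [], [], []
        for cube in cubes:
            tr = temporal_trend(cube, window)
            gr = apply_gradient_floor(
                spatial_gradient(period_mean(cube, window), grid), config.gradient_floor
            )
            floored_counts.append(gr.n_floored)
            trends.append(tr)
            speeds.append(climate_speed(tr, gr))
        ens = ensemble_mean_speed(speeds)

        thresholds = tuple(float(t) for t in config.thresholds)
        domains: list[str | RegionBox] = ["global"]
        if mask is not None:
            domains += ["land", "ocean"]
        domains += list(config.regions)
        summaries = {
            (d.name if isinstance(d, RegionBox) else d): summarize_exposure(
                ens, mask, d, thresholds
            )
            for d in domains
        }

        rates = [global_mean_temperature_rate(c, window) for c in cubes]
        thr = float(config.risk_threshold)
        glb = summarize_exposure(ens, mask, "global", (thr,))
        fracs = [glb.member_fractions[m.member_id][thr] for m in ens.members]
        point = RiskPoint(
            scenario=config.label,
            rate_mean=float(np.mean(rates)),
            rate_min=float(np.min(rates)),
            rate_max=float(np.max(rates)),
            exposed_mean=float(np.mean(fracs)),
            exposed_min=float(np.min(fracs)),
            exposed_max=float(np.max(fracs)),
            threshold_km_yr=thr,
        )
        robust = robustness_test(trends) if len(trends) >= 2 else None

        manifest = {
            "config": _manifest_config(config),
            "config_hash": _config_hash(config),
            "climspeed_version": __version__,
            "n_members": len(cubes),
            "floored_cells_per_member": floored_counts,
        }
        result = ScenarioResult(config, summaries, point, robust, ens, manifest)

        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name, summ in summaries.items():
                write_summary(summ, out / f"exposure_{config.label}_{name}.csv")
            write_summary(dataclasses.asdict(point), out / f"riskpoint_{config.label}.json")
            (out / f"manifest_{config.label}.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
            )
            _export_speed_netcdf(ens, out / f"speed_{config.label}.nc")
        return result
    except Exception as exc:
        exc.add_note(f"while running scenario {config.label!r}")
        raise


def _export_speed_netcdf(ens, path: Path) -> None:
    import xarray as xr

    g = ens.grid
    ds = xr.Dataset(
        {
            "speed_member": (
                ("member", "lat", "lon"),
                np.stack([m.speed_signed for m in ens.members]),
                {"units": "km yr-1", "long_name": "signed climate speed"},
            ),
            "direction_member": (
                ("member", "lat", "lon"),
                np.stack([m.direction for m in ens.members]),
                {"units": "degrees", "long_name": "climate velocity direction, clockwise from north"},
            ),
            "speed_ensemble_mean": (
                ("lat", "lon"),
                ens.ensemble_mean,
                {"units": "km yr-1"},
            ),
        },
        coords={
            "member": np.arange(ens.n_members),
            "lat": ("lat", g.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", g.lon_centers, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def risk_plane(
    points: Sequence[RiskPoint],
    lm_reference: ExposureSummary | Sequence[ExposureSummary] | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Assemble the scenario risk-plane table.

    x: global temperature-change rate (degC/yr); y: % of global area
    beyond the speed threshold.  When a natural-variability reference
    (e.g. preindustrial multi-period summaries) is given, its maximum
    exposure fraction at the threshold is attached to the table as the
    ``reference_max_exposed_pct`` attribute and drawn as a horizontal
    line on the optional plot.
    """
    if len(points) == 0:
        raise ValueError("need at least one risk point")
    df = pd.DataFrame([dataclasses.asdict(p) for p in points])
    df = df.sort_values("scenario", kind="stable").reset_index(drop=True)

    ref = None
    if lm_reference is not None:
        summaries = (
            [lm_reference] if isinstance(lm_reference, ExposureSummary) else list(lm_reference)
        )
        thr = points[0].threshold_km_yr
        ref = max(s.mean_fractions[thr] for s in summaries)
        df.attrs["reference_max_exposed_pct"] = ref

    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        for _, row in df.iterrows():
            ax.plot(
                [row.rate_min, row.rate_max], [row.exposed_mean] * 2, color="0.6", lw=1
            )
            ax.plot(
                [row.rate_mean] * 2, [row.exposed_min, row.exposed_max], color="0.6", lw=1
            )
            ax.plot(row.rate_mean, row.exposed_mean, "o", label=row.scenario)
        ax.axvline(0.0, ls="--", color="k", lw=0.8)
        if ref is not None:
            ax.axhline(ref, ls=":", color="k", lw=0.8)
        ax.set_xlabel("global temperature-change rate (°C/yr)")
        ax.set_ylabel(f"% area with |speed| > {points[0].threshold_km_yr:g} km/yr")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
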