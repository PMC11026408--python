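# Methods

## The climate-speed model

For a gridded annual-mean 2-m temperature field $T(t, \phi, \lambda)$
the climate velocity is the ratio of the temporal trend to the spatial
gradient, $\vec{C} = (dT/dt) \,/\, \vec{\nabla}T$; its magnitude, the
climate speed $|C| = |dT/dt| / |\nabla T|$, has units km/yr. The model
assumes the temperature change over the analysis window is adequately
described by a linear trend, and that the window-mean spatial field is
a meaningful backdrop for that trend. Both assumptions fail near sharp,
short-lived forcings (large volcanic eruptions), which is why window
selection excludes them (below).

Per ensemble member:

1. **Trend** — per-cell OLS slope of annual temperature against
   calendar year, years centered on the window mean for conditioning.
   Annual means are formed on read if the input is monthly (equal month
   weights; model calendars rarely justify day-count weighting, and the
   toggle exists at the reader level).
2. **Gradient** — computed on the *window-mean* field, not per year:
   the window climatology is the convention of the standard
   climate-velocity methodology and is far more stable against
   interannual noise than any single year's field.
3. **Speed** — $|{\rm slope}|/|\nabla T|$, K/yr ÷ K/km → km/yr, no unit
   inference. Sign = sign of the local trend. The ensemble mean is
   taken over the members' *signed* speeds after this calculation —
   averaging temperatures first would cancel internal variability and
   bias speeds low. Magnitude statistics (medians, exceedance) operate
   on per-member fields; each summary records which variant it reports.

### Spatial stencil

The 3×3 neighborhood-slope (Sobel) operator with normalization
$1/(8\Delta)$:

$$g_{\rm east}(j,i) = \frac{(T_{NE} + 2T_E + T_{SE}) - (T_{NW} + 2T_W + T_{SW})}{8\,\Delta x_j},$$

analogously for $g_{\rm north}$ with $\Delta y$. This normalization
makes the stencil an average of three centered differences, hence exact
on locally linear fields — the property that makes "Sobel" and "3×3
neighborhood slope" the same operator. Spacings are great-circle
distances: $\Delta y = R\,\Delta\phi$, $\Delta x_j = R\cos\phi_j\,
\Delta\lambda$ with $R$ = 6371 km (configurable). Longitude wraps
periodically; the first and last latitude rows use replicate padding,
are flagged, and are excluded from area statistics by default (maps are
unreliable at data edges regardless of stencil choice).

### Gradient floor

The velocity ratio is singular where $|\nabla T| \to 0$ (flat tropics,
uniform fields). Magnitudes are floored at ε = 1e-4 K/km by default —
bounding speeds at $|{\rm slope}|/\varepsilon$ — with every floored
cell flagged, counted in the run manifest, and excluded from the
default valid-cell set used by area statistics. Unbounded speeds in a
handful of degenerate cells would otherwise corrupt medians and
fractions. The floor is configurable and all downstream statistics
accept an explicit validity mask.

### Direction convention

The exported direction is the displacement an organism must make to
hold its temperature: down the spatial gradient under warming, up it
under cooling, i.e. $-\,{\rm sign}({\rm slope})\,\vec{\nabla}T /
|\nabla T|$, reported in degrees clockwise from north and NaN where the
gradient was floored. Directions are exported for context only; no
local vector statistics are computed, since trajectory-level use of
these vectors demands much finer grids than global model output offers.

## Exposure statistics

All fractions, medians and region means are **area-weighted** with
exact spherical band areas ($\propto \cos\phi$ for uniform spacing;
they sum to $4\pi R^2$ over a global grid). Unweighted cell counts on a
lat-lon grid would overrepresent the poles by an order of magnitude.

- Exceedance uses strict `>` ("beyond" a threshold). Default threshold
  set: 2, 5, 7, 10, 50 km/yr (terrestrial dispersal, intermediate,
  marine dispersal, extreme risk, invasive-extreme), all configurable.
- The weighted median is the smallest value whose cumulative weight
  reaches 50%, interpolating the midpoint of the straddling pair when
  the cumulative weight hits 50% exactly (so four equal cells
  {1,2,3,4} give 2.5).
- Land/ocean split: a cell is land when its land fraction ≥ 0.5
  (configurable cutoff); the mask enters statistics only, never field
  computation, because 2-m temperature is defined everywhere.
- Region boxes intersect the land mask by default (regional statistics
  here target terrestrial ecosystems); pass no mask for whole-box
  means. Displacement over a window = region-mean speed × window years.

### Robustness test

Per cell, $k$ = members agreeing with the majority trend sign (exact
zeros join neither side — conservative). Under the null hypothesis that
member signs are fair coins, $p = P(X \ge k) + P(X \le n-k)$,
$X \sim \mathrm{Bin}(n, 1/2)$, clipped to 1 on an even split; robust
⇔ $p < 0.1$. Two-sided is the default (the conservative reading; a
one-sided toggle exists). p-values are validated against exhaustive
enumeration over all $2^n$ sign patterns for $n \le 12$ in the tests.

## Window selection

Climate speeds are assessed over windows of ≥ 10 years (20 by default;
10 for fast-responding models whose cooling completes within a decade —
using 20 there would dilute the trend, and the window-length
sensitivity test in the suite demonstrates exactly this effect). Long
control runs are split into non-overlapping windows tiled from the
span's first year, advancing by the window length; any window with a
large eruption (≥ 10 Tg stratospheric sulfate) within 5 years of its
start or end (inclusive buffer on both sides) is dropped. A `listed`
mode validates a user-supplied window list against the eruption record
and warns about conflicts rather than silently accepting them, so
published window lists can be audited against a forcing record.

## Synthetic ensembles

The generator builds members as

$$T_m(t,j,i) = T_0 + G_y d_N(j) + G_x d_E(j,i) + \beta(j,i)\,(t-t_0)
  + \eta_m(t,j,i) + \textstyle\sum_k E_k(t)$$

with distances measured from the domain's south-west corner along great
circles at the cell's own latitude, so the designed gradients are exact
in K/km on the sphere (the zonal term's latitude dependence feeds a
$-G_x(\lambda-\lambda_0)\sin\phi$ correction into the true northward
gradient, which the emitted truth includes). $\eta$ is AR(1) in time
(innovation scale σ, lag-1 autocorrelation ρ, initialized from the
stationary distribution), independent across members via child streams
of one master seed — identical seeds are bit-identical. Eruptions are
$-A\,e^{-(t-t_e)/\tau}$ cooling spikes. Defaults (10 members, 20 years,
$G_y$ = 0.01 K/km, σ = 0.25 K, ρ = 0.5) represent a scenario-scale
ensemble with grid-point interannual variability and persistence
typical of annual-mean 2-m temperature.

What the generator does *not* emulate: spatially correlated variability
modes (ENSO-like patterns; optional Gaussian smoothing of innovations
is provided but off by default since uncorrelated noise is the cleaner
oracle), non-linear trends, topographic gradient structure, and
realistic coastline geometry (the mask is a rectangle). Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not fidelity of any particular Earth-system
simulation.

## Numerical choices

- OLS on integer years centered on the window mean; slope via a single
  tensordot (no per-cell Python loops).
- Bilinear remapping through `scipy.interpolate.RegularGridInterpolator`
  with one wrapped longitude column padded on each side; latitudes
  beyond the source rows replicate the edge row, so remapped values are
  bounded by local source extremes. A target more than 4× finer than
  the source warns (no information at that scale) but proceeds.
- NetCDF I/O through xarray's scipy backend (NetCDF3): plain,
  dependency-light files; time is stored as integer years, and readers
  also accept datetime axes (grouped by calendar year) and fractional
  monthly axes.
- Summary CSV/JSON serialization uses shortest round-trip float reprs,
  so write-then-read restores values bit-identically; scenario runs
  emit a manifest (resolved config minus the output path, its hash,
  package version, floored-cell counts) and reruns are byte-identical.

## Problem sizes

The validation suite and the acceptance script use 32×48 to 96×144
grids with 6–10 members and 20-year windows — sizes at which every
statistic is stable (the 96×144 noisy-recovery check resolves the
5 km/yr truth to well under 1%) while the whole suite runs in seconds.

## Known limitations

- Regular lat-lon grids only; no curvilinear/unstructured grids and no
  conservative regridding.
- The trend estimator is plain OLS (no Theil–Sen or autocorrelation-
  corrected variants); the robustness test, not the trend standard
  error, is the significance instrument.
- The bundled region file is an explicitly labeled placeholder;
  reproducing published regional numbers requires the authoritative
  region vertices and the corresponding model output.
- Speeds near coarse topography are known to be overestimated at
  global-model resolution; nothing in this package corrects for that.
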