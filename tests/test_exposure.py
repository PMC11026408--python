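import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import climspeed as cs
from climspeed.exposure import weighted_median
from climspeed.gradients import TrendField


def _equal_area_grid():
    """2x2 grid symmetric about the equator: all four cells equal area."""
    return cs.Grid(np.array([-10.0, 10.0]), np.array([0.0, 180.0]))


def _bruteforce_fraction(values, weights, cells, threshold):
    num = sum(w for v, w, c in zip(values, weights, cells) if c and abs(v) > threshold)
    den = sum(w for w, c in zip(weights, cells) if c)
    return 100.0 * num / den


def _bruteforce_weighted_median(values, weights):
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for i, (v, w) in enumerate(pairs):
        cum += w
        frac = cum / total
        if abs(frac - 0.5) < 1e-12 and i + 1 < len(pairs):
            return 0.5 * (v + pairs[i + 1][0])
        if frac >= 0.5:
            return v
    return pairs[-1][0]


class TestAreaFraction:
    def test_four_equal_cells_enumerated(self):
        grid = _equal_area_grid()
        speeds = np.array([[1.0, 3.0], [5.0, 7.0]])
        frac = cs.area_fraction_exceeding(speeds, grid, None, "global", 2.0)
        assert frac == pytest.approx(75.0)

    def test_threshold_zero_nonzero_field_is_100(self, small_grid, rng):
        speeds = 1.0 + rng.random(small_grid.shape)
        frac = cs.area_fraction_exceeding(speeds, small_grid, None, "global", 0.0)
        assert frac == pytest.approx(100.0, rel=1e-12)

    def test_threshold_above_max_is_0(self, small_grid, rng):
        speeds = rng.random(small_grid.shape)
        assert cs.area_fraction_exceeding(speeds, small_grid, None, "global", 10.0) == 0.0

    def test_strict_inequality_at_threshold(self):
        grid = _equal_area_grid()
        speeds = np.full(grid.shape, 10.0)
        assert cs.area_fraction_exceeding(speeds, grid, None, "global", 10.0) == 0.0

    def test_matches_bruteforce_on_random_domain(self, rng):
        grid = cs.regular_grid(5, 10)
        speeds = 20.0 * rng.random(grid.shape) - 10.0
        cells = rng.random(grid.shape) > 0.3
        mask = cs.SurfaceMask(grid, cells.astype(float))
        w = cs.cell_area_weights(grid)
        for thr in (0.5, 3.0, 8.0):
            expect = _bruteforce_fraction(
                speeds.ravel(), w.ravel(), cells.ravel(), thr
            )
            got = cs.area_fraction_exceeding(speeds, grid, mask, "land", thr)
            assert got == pytest.approx(expect, rel=1e-12)

    def test_fractions_monotone_in_threshold(self, rng):
        grid = cs.regular_grid(8, 12)
        speeds = 30.0 * rng.random(grid.shape)
        fracs = [
            cs.area_fraction_exceeding(speeds, grid, None, "global", t)
            for t in np.linspace(0, 30, 16)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_domain_raises(self, small_grid):
        mask = cs.SurfaceMask(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="empty domain"):
            cs.area_fraction_exceeding(
                np.ones(small_grid.shape), small_grid, mask, "land", 1.0
            )


class TestWeightedMedian:
    @pytest.mark.parametrize(
        "values,weights,expected",
        [
            ([1.0, 2.0, 9.0], [1, 1, 1], 2.0),  # odd equal-weight count
            ([4.0, 100.0, 200.0], [0.9, 0.05, 0.05], 4.0),  # dominant weight wins
            ([3.0, 3.0, 3.0], [0.2, 0.5, 0.3], 3.0),  # uniform field
            ([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], 2.5),  # even count interpolates
        ],
    )
    def test_hand_cases(self, values, weights, expected):
        assert weighted_median(np.array(values), np.array(weights)) == pytest.approx(expected)

    def test_matches_bruteforce_on_random_50_cell_domains(self, rng):
        for _ in range(20):
            v = rng.normal(size=50)
            w = rng.random(50) + 0.01
            assert weighted_median(v, w) == pytest.approx(
                _bruteforce_weighted_median(list(v), list(w)), rel=1e-12
            )

    def test_median_consistent_with_fraction(self, rng):
        # if less than half the area exceeds T then the median is <= T, and
        # vice versa: the two statistics describe the same distribution
        grid = cs.regular_grid(7, 9)
        speeds = 12.0 * rng.random(grid.shape)
        med = cs.weighted_median_speed(speeds, grid, None, "global")
        for t in (1.0, 4.0, 6.0, 9.0):
            frac = cs.area_fraction_exceeding(speeds, grid, None, "global", t)
            if frac < 50.0:
                assert med <= t
            elif frac > 50.0:
                assert med >= t

    def test_signed_vs_magnitude_flag(self):
        grid = _equal_area_grid()
        speeds = np.array([[-8.0, -6.0], [1.0, 2.0]])
        mag = cs.weighted_median_speed(speeds, grid, None, "global", use_magnitude=True)
        signed = cs.weighted_median_speed(speeds, grid, None, "global", use_magnitude=False)
        # four equal-weight cells: the 50% point falls exactly between the
        # 2nd and 3rd sorted values, so the median interpolates their midpoint
        assert mag == pytest.approx(0.5 * (2.0 + 6.0))
        assert signed == pytest.approx(0.5 * (-6.0 + 1.0))


class TestRegionMean:
    def test_uniform_12_km_yr_gives_240_km_displacement(self, small_grid):
        sp = cs.SpeedField(
            small_grid,
            np.full(small_grid.shape, 12.0),
            np.zeros(small_grid.shape),
            "m0",
            (2045, 2064),
        )
        ens = cs.ensemble_mean_speed([sp])
        region = cs.RegionBox("amazon-like", -15.0, 5.0, 280.0, 320.0)
        mean, displacement = cs.region_mean_speed(ens, region)
        assert mean == pytest.approx(12.0)
        assert displacement == pytest.approx(240.0)

    def test_single_cell_region_returns_cell_value(self, rng):
        grid = cs.regular_grid(10, 20)
        vals = rng.random(grid.shape)
        sp = cs.SpeedField(grid, vals, np.zeros(grid.shape), "m0", (2000, 2019))
        ens = cs.ensemble_mean_speed([sp])
        lat0, lon0 = grid.lat_centers[4], grid.lon_centers[7]
        region = cs.RegionBox("cell", lat0 - 1, lat0 + 1, lon0 - 1, lon0 + 1)
        mean, _ = cs.region_mean_speed(ens, region)
        assert mean == pytest.approx(abs(vals[4, 7]))

    def test_random_field_matches_bruteforce(self, rng):
        grid = cs.regular_grid(10, 20)
        vals = 5.0 * rng.standard_normal(grid.shape)
        sp = cs.SpeedField(grid, vals, np.zeros(grid.shape), "m0", (2000, 2019))
        ens = cs.ensemble_mean_speed([sp])
        region = cs.RegionBox("box", -40.0, 40.0, 30.0, 200.0)
        cells = region.cell_mask(grid)
        w = cs.cell_area_weights(grid)
        expect = float(np.sum(np.abs(vals)[cells] * w[cells]) / np.sum(w[cells]))
        mean, _ = cs.region_mean_speed(ens, region)
        assert mean == pytest.approx(expect, rel=1e-12)

    def test_disjoint_region_raises(self, small_grid):
        sp = cs.SpeedField(
            small_grid, np.ones(small_grid.shape), np.zeros(small_grid.shape), "m0", (2000, 2019)
        )
        ens = cs.ensemble_mean_speed([sp])
        with pytest.raises(ValueError, match="intersect"):
            cs.region_mean_speed(ens, cs.RegionBox("nowhere", 90.0, 90.0, 0.0, 1.0))


def _trend_fields(grid, signs):
    return [
        TrendField(grid, s * np.ones(grid.shape), (2000, 2019), f"m{i}")
        for i, s in enumerate(signs)
    ]


class TestRobustness:
    @pytest.mark.parametrize(
        "n_pos,n_neg,expected_p,robust",
        [
            (10, 0, 2 * 0.5**10, True),
            (7, 3, 0.34375, False),
            (9, 1, 0.021484375, True),
        ],
    )
    def test_closed_form_binomial_cases(self, small_grid, n_pos, n_neg, expected_p, robust):
        tfs = _trend_fields(small_grid, [0.01] * n_pos + [-0.01] * n_neg)
        rm = cs.robustness_test(tfs)
        assert rm.p_value[0, 0] == pytest.approx(expected_p, rel=1e-12)
        assert bool(rm.robust[0, 0]) is robust
        assert rm.agree_count[0, 0] == max(n_pos, n_neg)

    @pytest.mark.parametrize("n", [2, 3, 5, 8, 12])
    def test_matches_exhaustive_enumeration(self, small_grid, n):
        """p-values agree with direct enumeration over all 2^n sign patterns."""
        for n_pos in range(n + 1):
            tfs = _trend_fields(small_grid, [1.0] * n_pos + [-1.0] * (n - n_pos))
            p = cs.robustness_test(tfs).p_value[0, 0]
            k = max(n_pos, n - n_pos)
            count = sum(
                1
                for pattern in itertools.product([0, 1], repeat=n)
                if max(sum(pattern), n - sum(pattern)) >= k
            )
            assert p == pytest.approx(min(1.0, count / 2**n), rel=1e-12)

    def test_zero_trends_count_as_disagreement(self, small_grid):
        tfs = _trend_fields(small_grid, [1.0] * 8 + [0.0, 0.0])
        rm = cs.robustness_test(tfs)
        assert rm.agree_count[0, 0] == 8  # the two exact zeros join neither side
        # p for k=8 of n=10: 2 * P(X >= 8)
        assert rm.p_value[0, 0] == pytest.approx(2 * (45 + 10 + 1) / 1024, rel=1e-12)

    def test_one_sided_toggle(self, small_grid):
        tfs = _trend_fields(small_grid, [1.0] * 9 + [-1.0])
        two = cs.robustness_test(tfs, two_sided=True).p_value[0, 0]
        one = cs.robustness_test(tfs, two_sided=False).p_value[0, 0]
        assert one == pytest.approx(two / 2, rel=1e-12)

    def test_fewer_than_two_members_rejected(self, small_grid):
        with pytest.raises(ValueError, match="at least 2"):
            cs.robustness_test(_trend_fields(small_grid, [1.0]))


class TestPeriodDistribution:
    def test_stationary_noiseless_cube_all_periods_zero(self):
        cfg = cs.SyntheticConfig(
            nlat=12, nlon=18, trend=0.0, noise_sigma=0.0, n_members=1, n_years=60,
            start_year=1000,
        )
        cubes, mask, _ = cs.generate_ensemble(cfg)
        periods = [(1000, 1019), (1020, 1039), (1040, 1059)]
        rows, max_fracs = cs.speed_distribution_over_periods(
            cubes[0], periods, mask, "global", (2.0, 10.0)
        )
        assert len(rows) == 3
        for _, summ in rows:
            assert summ.mean_of_member_medians == pytest.approx(0.0, abs=1e-9)
        assert max_fracs[2.0] == 0.0

    def test_period_with_injected_trend_stands_out(self):
        cfg = cs.SyntheticConfig(
            nlat=12, nlon=18, trend=0.0, noise_sigma=0.0, n_members=1, n_years=60,
            start_year=1000,
        )
        cubes, mask, _ = cs.generate_ensemble(cfg)
        v = cubes[0].values.copy()
        sel = (cubes[0].years >= 1020) & (cubes[0].years <= 1039)
        v[sel] += 0.05 * np.arange(sel.sum())[:, None, None]
        cube = cs.TemperatureCube(cubes[0].grid, cubes[0].years, v)
        rows, max_fracs = cs.speed_distribution_over_periods(
            cube, [(1000, 1019), (1020, 1039), (1040, 1059)], mask, "global", (2.0,)
        )
        medians = [s.mean_of_member_medians for _, s in rows]
        assert medians[1] > medians[0] and medians[1] > medians[2]
        assert max_fracs[2.0] == rows[1][1].mean_fractions[2.0]


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_fraction_median_consistency_property(seed):
    """Across random speed fields the exceedance fraction at the median is
    never above 50% (strict '>') and the fraction at any value below the
    median is at least 50%."""
    rng = np.random.default_rng(seed)
    grid = cs.regular_grid(6, 8)
    speeds = 10.0 * rng.random(grid.shape)
    med = cs.weighted_median_speed(speeds, grid, None, "global")
    assert cs.area_fraction_exceeding(speeds, grid, None, "global", med) <= 50.0
    below = med - 1e-9
    if below > 0:
        assert cs.area_fraction_exceeding(speeds, grid, None, "global", below) >= 50.0 - 1e-9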