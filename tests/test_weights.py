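"""Inhabitability mask, topo regression, density gradient, market potential."""

import math

import numpy as np
import pytest

from dasypop import (
    FitError,
    GridSpec,
    InhabitabilityConfig,
    LabelRaster,
    TravelRangeSchedule,
    ValueRaster,
    fit_topo_relation,
    inhabitability_mask,
    market_potential,
    topo_weight,
    travel_range,
    urban_distance_weight,
)
from dasypop.weights import RegionTopoFit


@pytest.fixture
def spec():
    return GridSpec(5, 5)


class TestInhabitability:
    def test_high_elevation_excluded(self, spec):
        z = np.full(spec.shape, 100.0)
        z[2, 2] = 3600.0
        w0 = inhabitability_mask(ValueRaster(spec, z)).values
        assert w0[2, 2] == 0.0
        assert w0[0, 0] == 1.0

    def test_small_water_patch_kept_large_excluded(self):
        # 0.5-km cells: a 3-pixel patch (0.75 km2) stays, 5 pixels (1.25 km2) go
        spec = GridSpec(5, 5, cell_size_km=0.5)
        z = np.zeros(spec.shape)
        water = np.zeros(spec.shape, bool)
        water[0, 0:3] = True
        water[4, 0:5] = True
        w0 = inhabitability_mask(ValueRaster(spec, z), water_mask=water).values
        assert w0[0, 0:3].min() == 1.0
        assert w0[4, 0:5].max() == 0.0

    def test_low_population_tract_masked_by_division_cutoff(self, spec):
        z = np.zeros(spec.shape)
        tracts = np.ones(spec.shape, dtype=int)
        tracts[:, 3:] = 2
        divisions = np.ones(spec.shape, dtype=int)
        cfg = InhabitabilityConfig(cutoff_population_by_division={1: 2000})
        w0 = inhabitability_mask(
            ValueRaster(spec, z),
            tract_labels=LabelRaster(spec, tracts),
            tract_populations={1: 1500.0, 2: 9000.0},
            division_labels=LabelRaster(spec, divisions),
            config=cfg,
        ).values
        assert w0[tracts == 1].max() == 0.0
        assert w0[tracts == 2].min() == 1.0

    def test_protected_pixels_excluded(self, spec):
        z = np.zeros(spec.shape)
        prot = np.zeros(spec.shape, bool)
        prot[1, 1] = True
        w0 = inhabitability_mask(ValueRaster(spec, z), protected_mask=prot).values
        assert w0[1, 1] == 0.0


class TestTopoFit:
    def test_noise_free_relation_recovered(self):
        z = np.linspace(0, 2000, 10)
        pd_ = np.exp(-0.001 * z + 5)
        fit = fit_topo_relation(pd_, z, region_id=3)
        assert fit.slope == pytest.approx(-0.001, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-10)
        assert fit.weighted

    def test_flat_elevation_is_degenerate(self):
        with pytest.raises(FitError):
            fit_topo_relation([10, 20, 30], [500.0, 500.0, 500.0])

    def test_too_few_counties(self):
        with pytest.raises(FitError):
            fit_topo_relation([10, 20], [0.0, 100.0])

    def test_monte_carlo_recovery_within_15_percent(self):
        slopes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.uniform(0, 2000, 40)
            pd_ = np.exp(-0.0015 * z + 4.5 + rng.normal(0, 0.3, 40))
            slopes.append(fit_topo_relation(pd_, z).slope)
        assert abs(np.median(slopes) / -0.0015 - 1) < 0.15

    def test_insignificant_slope_flagged_unweighted(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0, 2000, 30)
        pd_ = np.exp(rng.normal(4, 0.5, 30))  # no elevation signal
        fit = fit_topo_relation(pd_, z)
        assert not fit.weighted

    def test_elevation_band_restricts_counties(self):
        z = np.concatenate([np.linspace(0, 90, 5), np.linspace(100, 300, 5)])
        pd_ = np.exp(-0.002 * z + 6)
        fit = fit_topo_relation(pd_, z, elevation_band=(100, 301))
        assert fit.n_fit == 5


class TestTopoWeight:
    def test_zero_slope_gives_unit_weight(self, spec):
        z = np.random.default_rng(0).uniform(0, 2000, spec.shape)
        fit = RegionTopoFit(1, 0.0, 4.0, 10, 0.001, 0.9)
        assert np.all(topo_weight(ValueRaster(spec, z), fit).values == 1.0)

    def test_closed_form(self, spec):
        z = np.full(spec.shape, 1000.0)
        fit = RegionTopoFit(1, -0.001, 4.0, 10, 0.001, 0.9)
        w1 = topo_weight(ValueRaster(spec, z), fit).values
        assert w1[0, 0] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_unweighted_region_passes_through(self, spec):
        z = np.full(spec.shape, 2500.0)
        fit = RegionTopoFit(1, -0.002, 4.0, 10, 0.4, 0.1, weighted=False)
        assert np.all(topo_weight(ValueRaster(spec, z), fit).values == 1.0)


class TestUrbanDistanceWeight:
    def test_flat_gradient_limit(self):
        px = np.array([(0, 0), (0, 3), (4, 4)])
        assert np.all(urban_distance_weight(px, (0, 0), 0.0) == 1.0)

    def test_closed_form_inverse(self):
        px = np.array([(0, 2)])
        w = urban_distance_weight(px, (0, 0), 1.0)
        assert w[0] == pytest.approx(0.5)

    def test_matches_power_law_and_monotone(self):
        px = np.array([(0, 1), (0, 2), (0, 4)])
        w = urban_distance_weight(px, (0, 0), 0.10)
        np.testing.assert_allclose(w, np.array([1.0, 2.0, 4.0]) ** -0.10, rtol=1e-14)
        assert np.all(np.diff(w) < 0)

    def test_center_pixel_clamped_at_half_cell(self):
        w = urban_distance_weight(np.array([(0, 0)]), (0, 0), 1.0)
        assert w[0] == pytest.approx(2.0)  # (cell/2)^-1


class TestTravelRange:
    def test_anchor_years(self):
        assert travel_range(1790) == 30.0
        assert travel_range(2000) == 100.0

    def test_log_linear_midpoint(self):
        assert travel_range(1895) == pytest.approx(math.sqrt(30 * 100), rel=1e-12)

    def test_extrapolation_clamped(self):
        assert travel_range(1700) == 30.0
        assert travel_range(2050) == 100.0

    def test_invalid_anchor_rejected(self):
        from dasypop import ConfigError

        with pytest.raises(ConfigError):
            TravelRangeSchedule(anchors={1790: -5.0})


class TestMarketPotential:
    def test_single_source_distance_cancels(self):
        px = np.array([(0, 0), (3, 3), (9, 9)])
        w = market_potential(px, np.array([(5, 5)]), np.array([8000.0]), d_t_km=100)
        np.testing.assert_allclose(w, 8000.0)

    def test_equal_populations_give_uniform_weight(self):
        px = np.array([(i, j) for i in range(5) for j in range(5)])
        centers = np.array([(0, 0), (4, 4)])
        w = market_potential(px, centers, np.array([5000.0, 5000.0]), d_t_km=100)
        np.testing.assert_allclose(w, 5000.0)

    def test_matches_brute_force_double_loop(self):
        centers = np.array([(0, 0), (2, 4), (4, 1)])
        pops = np.array([3000.0, 12_000.0, 5000.0])
        px = np.array([(i, j) for i in range(5) for j in range(5)])
        got = market_potential(px, centers, pops, d_t_km=100.0)
        for k, (r, c) in enumerate(px):
            num = den = 0.0
            for (ur, uc), p in zip(centers, pops):
                d = max(math.hypot(r - ur, c - uc), 0.5)
                num += p / d**2
                den += 1 / d**2
            assert got[k] == pytest.approx(num / den, rel=1e-13)

    def test_out_of_range_pixels_get_neutral_weight(self):
        px = np.array([(0, 0), (0, 40)])
        w = market_potential(px, np.array([(0, 0)]), np.array([9000.0]), d_t_km=10)
        assert w[0] == 9000.0
        assert w[1] == 1.0

    def test_bounded_by_population_range(self):
        rng = np.random.default_rng(3)
        centers = rng.integers(0, 20, (6, 2))
        pops = rng.uniform(2500, 50_000, 6)
        px = np.array([(i, j) for i in range(20) for j in range(20)])
        w = market_potential(px, centers, pops, d_t_km=100)
        assert w.min() >= pops.min() - 1e-9
        assert w.max() <= pops.max() + 1e-9
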