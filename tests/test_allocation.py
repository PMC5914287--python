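"""Eq.-style normalized-product allocation and the M1–M5 model family."""

import numpy as np
import pytest

from dasypop import AllocationError, ModelSpec, Study, allocate_zone, run_history, run_model, zonal_sum


def study_with_true_parameters(world) -> Study:
    """Fresh study bundle carrying the generative parameters instead of fits."""
    s = world.study
    return Study(
        spec=s.spec,
        county_labels=s.county_labels,
        division_labels=s.division_labels,
        region_labels=s.region_labels,
        elevation=s.elevation,
        county_census=s.county_census,
        registry=s.registry,
        decades=s.decades,
        baseline_decade=s.baseline_decade,
        water_mask=s.water_mask,
        protected_mask=s.protected_mask,
        travel_schedule=s.travel_schedule,
        scaling_fits=world.true_scaling_fits,
        topo_fits=world.true_topo_fits,
    )


class TestAllocateZone:
    def test_equal_weights_uniform(self):
        vals, fb = allocate_zone(100.0, np.ones(4))
        np.testing.assert_allclose(vals, 25.0)
        assert not fb

    def test_proportional_shares(self):
        vals, _ = allocate_zone(100.0, np.ones(3), np.array([2.0, 1.0, 1.0]), s=1.0)
        np.testing.assert_allclose(vals, [50.0, 25.0, 25.0])

    def test_matches_brute_force_normalized_product(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 20
            w0 = (rng.random(n) > 0.2).astype(float)
            w1 = rng.uniform(0.1, 3, n)
            w2 = rng.uniform(0.5, 5000, n)
            s, d = rng.uniform(0, 3, 2)
            p_z = rng.uniform(0, 1e5)
            got, fb = allocate_zone(p_z, w0, w1, w2, s, d)
            w = w0 * w1**s * w2**d
            np.testing.assert_allclose(got, p_z * w / w.sum(), rtol=1e-12)
            assert got.sum() == pytest.approx(p_z, rel=1e-12)

    def test_zero_weight_zone_falls_back_to_uniform(self):
        vals, fb = allocate_zone(90.0, np.zeros(3))
        np.testing.assert_allclose(vals, 30.0)
        assert fb

    def test_empty_zone_with_population_rejected(self):
        with pytest.raises(AllocationError):
            allocate_zone(10.0, np.zeros(0))


class TestModels:
    def test_m1_is_homogeneous_within_counties(self, small_world):
        study = small_world.study
        res = run_model(study, ModelSpec("M1"), 2000)
        for cid in study.county_ids()[:3]:
            sel = study.county_labels.labels == cid
            vals = res.population.values[sel]
            assert np.allclose(vals, vals[0])
            assert vals.sum() == pytest.approx(study.county_census.population(int(cid), 2000), rel=1e-9)

    def test_m2_splits_urban_and_rural_uniformly(self, small_world):
        study = small_world.study
        res = run_model(study, ModelSpec("M2"), 2000)
        urban = study.extent_raster(2000).labels
        for ua in study.registry.existing_in(2000):
            sel = urban == ua.urban_id
            vals = res.population.values[sel]
            assert np.allclose(vals, vals[0])
            assert vals.sum() == pytest.approx(ua.population(2000), rel=1e-9)

    @pytest.mark.parametrize("model", ["M1", "M2", "M3", "M4", "M5"])
    def test_county_conservation_every_model(self, small_world, model):
        study = small_world.study
        for decade in study.decades:
            res = run_model(study, ModelSpec(model, s=1.0, d=0.6), decade)
            sums = zonal_sum(res.population, study.county_labels)
            for cid, p_t in study.county_census.populations(decade).items():
                assert sums[cid] == pytest.approx(p_t, rel=1e-6)

    def test_model_nesting_s0_d0(self, small_world):
        study = small_world.study
        m3 = run_model(study, ModelSpec("M3"), 2000).population.values
        m4_s0 = run_model(study, ModelSpec("M4", s=0.0), 2000).population.values
        np.testing.assert_array_equal(m3, m4_s0)
        m4 = run_model(study, ModelSpec("M4", s=1.3), 2000).population.values
        m5_d0 = run_model(study, ModelSpec("M5", s=1.3, d=0.0), 2000).population.values
        np.testing.assert_array_equal(m4, m5_d0)

    def test_generative_self_consistency(self, noise_free_world):
        """M5 with the true parameters reproduces ground truth bit-exactly
        when extents are exact."""
        world = noise_free_world
        study = study_with_true_parameters(world)
        cfg = world.config
        for decade in (1900, 1950, 2000):
            res = run_model(study, ModelSpec("M5", s=cfg.true_s, d=cfg.true_d), decade)
            np.testing.assert_array_equal(
                res.population.values, world.truth_by_decade[decade].values
            )

    def test_weight_rescaling_within_zone_is_invariant(self, small_world):
        """Multiplying a weight layer by a constant inside one allocation
        zone leaves the output unchanged (max-normalization is cosmetic)."""
        study = small_world.study
        base = run_model(study, ModelSpec("M4", s=1.0), 2000).population.values
        w1 = study.ensure_w1()
        try:
            scaled = w1.values.copy()
            cid = int(study.county_ids()[0])
            scaled[study.county_labels.labels == cid] *= 37.5
            study._w1 = type(w1)(w1.spec, scaled)
            got = run_model(study, ModelSpec("M4", s=1.0), 2000).population.values
        finally:
            study._w1 = w1
        np.testing.assert_allclose(got, base, rtol=1e-9)


class TestHistory:
    def test_per_decade_conservation_and_skip_list(self, small_world):
        study = small_world.study
        results = run_history(study, ModelSpec("M3"), skip=(1980,))
        assert 1980 not in results
        assert set(results) == {1970, 1990, 2000}
        for t, res in results.items():
            national = float(np.nansum(res.population.values))
            expected = sum(study.county_census.populations(t).values())
            assert national == pytest.approx(expected, rel=1e-9)

    def test_rerun_is_bit_identical(self, small_world):
        study = small_world.study
        a = run_history(study, ModelSpec("M5", s=1.0, d=0.6))
        b = run_history(study, ModelSpec("M5", s=1.0, d=0.6))
        for t in a:
            np.testing.assert_array_equal(a[t].population.values, b[t].population.values)
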