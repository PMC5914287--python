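"""MARE scoring, cutoff/exponent selection, model effectiveness."""

import numpy as np
import pytest

from dasypop import (
    DasypopError,
    GridSpec,
    InhabitabilityConfig,
    ModelSpec,
    WorldConfig,
    generate_world,
    mare,
    mare_against_units,
    model_effectiveness,
    run_model,
    select_cutoff_population,
    validate_models,
)
from dasypop.errors import ConfigError
from dasypop.validation import calibrate_exponent


class TestMare:
    def test_perfect_model_scores_zero(self):
        m = o = {1: 100.0, 2: 300.0}
        assert mare(m, o)[0] == 0.0

    def test_doubling_scores_one(self):
        o = {1: 100.0, 2: 300.0}
        m = {k: 2 * v for k, v in o.items()}
        assert mare(m, o)[0] == pytest.approx(1.0)

    def test_hand_example(self):
        m = {1: 110.0, 2: 80.0, 3: 400.0}
        o = {1: 100.0, 2: 100.0, 3: 500.0}
        score, n = mare(m, o)
        assert score == pytest.approx(0.1667, abs=5e-5)
        assert n == 3

    def test_scale_free(self):
        rng = np.random.default_rng(0)
        o = {i: float(v) for i, v in enumerate(rng.uniform(10, 1000, 20), 1)}
        m = {i: float(v) for i, v in enumerate(rng.uniform(10, 1000, 20), 1)}
        a = mare(m, o)[0]
        b = mare({k: 7 * v for k, v in m.items()}, {k: 7 * v for k, v in o.items()})[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_small_units_filtered_by_min_area(self):
        m = {1: 110.0, 2: 999.0}
        o = {1: 100.0, 2: 100.0}
        areas = {1: 10.0, 2: 0.5}
        score, n = mare(m, o, areas, min_area_km2=1.0)
        assert n == 1
        assert score == pytest.approx(0.1)

    def test_zero_observed_units_excluded(self):
        score, n = mare({1: 5.0, 2: 110.0}, {1: 0.0, 2: 100.0})
        assert n == 1
        assert score == pytest.approx(0.1)

    def test_no_retained_units_is_an_error(self):
        with pytest.raises(DasypopError):
            mare({1: 5.0}, {1: 0.0})


class TestSelection:
    def test_cutoff_flat_scores_tie_to_smallest(self):
        assert select_cutoff_population(lambda c: 0.5) == 1000

    def test_cutoff_argmin_of_division_scores(self):
        # per-candidate division MAREs with a clear interior minimum
        table = {1000: 0.59, 1500: 0.60, 2000: 0.61, 2500: 0.64, 3000: 0.70}
        assert select_cutoff_population(table.__getitem__) == 1000
        table2 = {1000: 0.94, 1500: 0.64, 2000: 0.53, 2500: 0.58, 3000: 0.67}
        assert select_cutoff_population(table2.__getitem__) == 2000

    def test_exponent_argmin_on_published_style_rows(self):
        # monotone-increasing row: the weakest weighting wins
        s_row = {0.2: 0.73, 0.4: 0.74, 0.6: 0.75, 0.8: 0.76, 1.0: 0.78,
                 2.0: 0.86, 3.0: 0.95}
        assert calibrate_exponent(s_row.__getitem__, tuple(s_row)) == 0.2
        # interior minimum with a tie at the bottom end: smaller value wins
        d_row = {1.2: 1.117, 1.4: 1.113, 1.6: 1.111, 1.8: 1.110, 2.0: 1.110}
        assert calibrate_exponent(d_row.__getitem__, tuple(d_row)) == 1.8

    def test_exponent_single_point_grid(self):
        assert calibrate_exponent(lambda g: 1.0, (0.7,)) == 0.7

    def test_exponent_tie_goes_to_smaller(self):
        assert calibrate_exponent(lambda g: 0.4, (0.2, 0.4, 0.6)) == 0.2

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            calibrate_exponent(lambda g: 0.0, ())


class TestCutoffRecovery:
    def test_masking_sparse_tracts_lowers_error(self):
        """On a world whose truth drains population out of a subset of
        tracts, running M3 with a tract-population cutoff that excludes
        them scores better than no cutoff at all."""
        cfg = WorldConfig(
            grid=GridSpec(60, 60), n_divisions=1, counties_per_division=4,
            tracts_per_county=9, decades=[1990, 2000],
            sparse_tract_fraction=0.4, seed=5,
        )
        world = generate_world(cfg)
        study = world.study

        def evaluate(cutoff: float) -> float:
            study.inhabit_config = InhabitabilityConfig(
                cutoff_population_by_division={1: cutoff}
            )
            study._w0 = None  # rebuild the mask under this cutoff
            res = run_model(study, ModelSpec("M3"), 2000)
            return mare_against_units(res, study.tract_labels, study.tract_census, 2000)[0]

        no_cutoff = evaluate(0.0)
        sparse_pops = [
            study.tract_census.population(t, 2000) for t in world.sparse_tract_ids
        ]
        cutoff = float(np.percentile(sparse_pops, 90) * 1.01)
        with_cutoff = evaluate(cutoff)
        study.inhabit_config = InhabitabilityConfig()
        study._w0 = None
        assert with_cutoff < no_cutoff


class TestEffectiveness:
    def test_published_style_national_row(self):
        mares = {"M1": 6.96, "M2": 5.13, "M3": 1.55, "M4": 1.55, "M5": 1.54}
        deltas = model_effectiveness(mares)
        assert deltas["M1-M2"] == pytest.approx(1.83)
        assert deltas["M2-M3"] == pytest.approx(3.58)
        assert deltas["M3-M4"] == pytest.approx(0.00, abs=1e-12)
        assert deltas["M4-M5"] == pytest.approx(0.01)

    def test_constant_mare_gives_zero_deltas(self):
        deltas = model_effectiveness({m: 0.8 for m in ("M1", "M2", "M3", "M4", "M5")})
        assert all(v == 0.0 for v in deltas.values())

    def test_random_vector_matches_consecutive_differences_and_telescopes(self):
        rng = np.random.default_rng(4)
        vals = dict(zip(("M1", "M2", "M3", "M4", "M5"), rng.uniform(0.5, 8, 5)))
        deltas = model_effectiveness(vals)
        keys = list(vals)
        for (a, b), d in zip(zip(keys, keys[1:]), deltas.values()):
            assert d == pytest.approx(vals[a] - vals[b])
        assert sum(deltas.values()) == pytest.approx(vals["M1"] - vals["M5"])

    def test_missing_model_flagged(self):
        with pytest.raises(ConfigError, match="M3"):
            model_effectiveness({"M1": 1.0, "M2": 0.9, "M4": 0.8, "M5": 0.7})


class TestValidateModels:
    def test_report_contains_all_models_and_divisions(self, small_world):
        report = validate_models(small_world.study, s=1.0, d=0.6)
        assert set(report.mare_by_model) == {"M1", "M2", "M3", "M4", "M5"}
        assert set(report.effectiveness) == {"M1-M2", "M2-M3", "M3-M4", "M4-M5"}
        assert all(v >= 0 for v in report.mare_by_model.values())
        assert all(n > 0 for n in report.n_units_by_model.values())
        d = report.to_dict()
        assert d["decade"] == small_world.study.baseline_decade

    def test_subdivision_level_scoring(self, small_world):
        report = validate_models(small_world.study, s=1.0, d=0.6, level="subdivision",
                                 models=("M1", "M3"))
        assert report.mare_by_model["M3"] <= report.mare_by_model["M1"]
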