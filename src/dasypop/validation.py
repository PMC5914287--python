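"""Accuracy scoring (MARE), cutoff/exponent calibration, model effectiveness.

Products are scored against reference census units finer than the county
input — census tracts primarily, county subdivisions as a coarser check —
with mean absolute relative error

    MARE = (1/N_c) * sum_c |M_c - O_c| / O_c

over units of at least 1 km² (the product's resolution precludes smaller
units). Zero-population reference units are excluded rather than treated
as errors. MARE is scale-free.

Calibration is sequential grid search per division, mirroring the nested
model construction: the topographic exponent s is chosen under M4 (no d),
then the desirability exponent d under M5 with s fixed. Ties go to the
smaller candidate. Model effectiveness is the MARE reduction of each model
over its next-simpler neighbor; the deltas telescope to MARE(M1)-MARE(M5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import allocation as al
from .errors import ConfigError, DasypopError
from .grids import LabelRaster, zonal_sum
from .study import Study

__all__ = [
    "mare",
    "mare_against_units",
    "select_cutoff_population",
    "calibrate_exponent",
    "calibrate_study",
    "model_effectiveness",
    "ValidationReport",
    "S_GRID",
    "D_GRID",
    "D_GRID_COARSE",
]

# published calibration grids: s on [0.2, 3]; d extends below 0.2 because
# desirability is far more sensitive to its exponent at the low end
S_GRID = (0.2, 0.4, 0.6, 0.8, 1.0, 1.4, 1.5, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0)
D_GRID = (0.02, 0.04, 0.06, 0.08, 0.10, 0.20, 0.40, 0.60, 0.80,
          1.00, 1.20, 1.40, 1.60, 1.80, 2.00)
D_GRID_COARSE = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0)

CUTOFF_CANDIDATES = (1000, 1500, 2000, 2500, 3000)


def mare(
    modeled: dict[int, float],
    observed: dict[int, float],
    unit_areas: dict[int, float] | None = None,
    min_area_km2: float = 1.0,
) -> tuple[float, int]:
    """Mean absolute relative error over matching reference units.

    Units smaller than ``min_area_km2`` are excluded, as are units with
    zero observed population (the relative error is undefined there).
    Returns (MARE, number of units evaluated).
    """
    errors = []
    for uid, o_c in observed.items():
        if unit_areas is not None and unit_areas.get(uid, np.inf) < min_area_km2:
            continue
        if o_c <= 0:
            continue
        m_c = modeled.get(uid, 0.0)
        errors.append(abs(m_c - o_c) / o_c)
    if not errors:
        raise DasypopError("no reference units retained for MARE")
    return float(np.mean(errors)), len(errors)


def mare_against_units(
    result: al.AllocationResult,
    unit_labels: LabelRaster,
    unit_census,
    decade: int,
    min_area_km2: float = 1.0,
    unit_subset: "set[int] | None" = None,
) -> tuple[float, int]:
    """Aggregate a population raster by reference units and score it."""
    modeled = zonal_sum(result.population, unit_labels)
    observed = unit_census.populations(decade)
    if unit_subset is not None:
        observed = {u: v for u, v in observed.items() if u in unit_subset}
    areas = None
    if "area_km2" in unit_census.df.columns:
        sel = unit_census.df[unit_census.df.decade == decade]
        areas = dict(zip(sel.unit_id.astype(int), sel.area_km2.astype(float)))
    return mare(modeled, observed, areas, min_area_km2)


def select_cutoff_population(
    evaluator,
    candidates: "tuple[int, ...]" = CUTOFF_CANDIDATES,
) -> int:
    """Tract-population cutoff minimizing the evaluator's MARE.

    ``evaluator(candidate)`` must run the inhabitability-masked pipeline
    (M3) with that cutoff and return the division's MARE. Ties go to the
    smaller cutoff.
    """
    if not candidates:
        raise ConfigError("no cutoff candidates")
    scores = {c: evaluator(c) for c in candidates}
    return min(sorted(scores), key=lambda c: scores[c])


def calibrate_exponent(evaluator, grid: "tuple[float, ...]") -> float:
    """Grid value minimizing the evaluator's MARE; ties go to the smaller value."""
    if not grid:
        raise ConfigError("empty calibration grid")
    scores = {g: evaluator(g) for g in grid}
    return min(sorted(scores), key=lambda g: scores[g])


def _division_tract_sets(study: Study) -> dict[int, set[int]]:
    """Tract ids grouped by the division they sit in."""
    out: dict[int, set[int]] = {}
    tl = study.tract_labels.labels
    dl = study.division_labels.labels
    for tid in study.tract_labels.ids():
        sel = tl == tid
        out.setdefault(int(dl[sel][0]), set()).add(int(tid))
    return out


def calibrate_study(
    study: Study,
    decade: int | None = None,
    s_grid: "tuple[float, ...]" = S_GRID,
    d_grid: "tuple[float, ...]" = D_GRID,
    joint: bool = False,
    min_area_km2: float = 1.0,
) -> tuple[dict[int, float], dict[int, float]]:
    """Sequential per-division calibration of (s, d) on tract-level MARE.

    Runs M4 across the s grid, picks each division's argmin, then runs M5
    across the d grid with s fixed. ``joint=True` instead searches the
    full s×d product under M5 (slower; available because sequential search
    can in principle miss interactions).
    Returns ({division: s}, {division: d}).
    """
    if study.tract_labels is None or study.tract_census is None:
        raise ConfigError("calibration needs tract labels and a tract census table")
    decade = decade if decade is not None else study.baseline_decade
    by_div = _division_tract_sets(study)

    def _mares(result) -> dict[int, float]:
        return {
            div: mare_against_units(result, study.tract_labels, study.tract_census,
                                    decade, min_area_km2, unit_subset=tracts)[0]
            for div, tracts in by_div.items()
        }

    if joint:
        best: dict[int, tuple[float, float, float]] = {}
        for s in s_grid:
            for d in d_grid:
                res = al.run_model(study, al.ModelSpec("M5", s=s, d=d), decade)
                for div, m in _mares(res).items():
                    if div not in best or m < best[div][0]:
                        best[div] = (m, s, d)
        return ({div: v[1] for div, v in best.items()},
                {div: v[2] for div, v in best.items()})

    s_scores = {
        s: _mares(al.run_model(study, al.ModelSpec("M4", s=s), decade)) for s in s_grid
    }
    s_by_div = {
        div: min(sorted(s_grid), key=lambda s: s_scores[s][div]) for div in by_div
    }
    d_scores = {
        d: _mares(al.run_model(study, al.ModelSpec("M5", s=s_by_div, d=d), decade))
        for d in d_grid
    }
    d_by_div = {
        div: min(sorted(d_grid), key=lambda d: d_scores[d][div]) for div in by_div
    }
    return s_by_div, d_by_div


def model_effectiveness(mare_by_model: dict[str, float]) -> dict[str, float]:
    """MARE reduction of each model over its next-simpler neighbor.

    Returns {'M1-M2': ..., 'M2-M3': ..., 'M3-M4': ..., 'M4-M5': ...};
    a missing model raises with the gap named.
    """
    out: dict[str, float] = {}
    for a, b in zip(al.MODELS, al.MODELS[1:]):
        if a not in mare_by_model or b not in mare_by_model:
            missing = a if a not in mare_by_model else b
            raise ConfigError(f"model_effectiveness: MARE for {missing} missing")
        out[f"{a}-{b}"] = mare_by_model[a] - mare_by_model[b]
    return out


@dataclass
class ValidationReport:
    """MARE by model and stratum plus effectiveness deltas and calibrated tables."""

    decade: int
    mare_by_model: dict[str, float] = field(default_factory=dict)
    n_units_by_model: dict[str, int] = field(default_factory=dict)
    mare_by_division: dict[str, dict[int, float]] = field(default_factory=dict)
    effectiveness: dict[str, float] = field(default_factory=dict)
    s_by_division: dict[int, float] = field(default_factory=dict)
    d_by_division: dict[int, float] = field(default_factory=dict)
    min_area_km2: float = 1.0

    def to_dict(self) -> dict:
        return {
            "decade": self.decade,
            "min_area_km2": self.min_area_km2,
            "mare_by_model": self.mare_by_model,
            "n_units_by_model": self.n_units_by_model,
            "mare_by_division": {
                m: {str(k): v for k, v in d.items()}
                for m, d in self.mare_by_division.items()
            },
            "effectiveness": self.effectiveness,
            "s_by_division": {str(k): v for k, v in self.s_by_division.items()},
            "d_by_division": {str(k): v for k, v in self.d_by_division.items()},
        }


def validate_models(
    study: Study,
    decade: int | None = None,
    models: "tuple[str, ...]" = al.MODELS,
    s: "float | dict[int, float]" = 1.0,
    d: "float | dict[int, float]" = 1.0,
    level: str = "tract",
    min_area_km2: float = 1.0,
) -> ValidationReport:
    """Score every requested model at one decade against tract (or
    subdivision) reference units."""
    decade = decade if decade is not None else study.baseline_decade
    if level == "tract":
        labels, census = study.tract_labels, study.tract_census
    elif level == "subdivision":
        labels, census = study.subdivision_labels, study.subdivision_census
    else:
        raise ConfigError(f"unknown validation level {level!r}")
    if labels is None or census is None:
        raise ConfigError(f"study lacks {level} reference data")
    report = ValidationReport(decade=decade, min_area_km2=min_area_km2)
    by_div = _division_tract_sets(study) if level == "tract" else None
    for m in models:
        res = al.run_model(study, al.ModelSpec(m, s=s, d=d), decade)
        report.mare_by_model[m], report.n_units_by_model[m] = mare_against_units(
            res, labels, census, decade, min_area_km2
        )
        if by_div:
            report.mare_by_division[m] = {
                div: mare_against_units(res, labels, census, decade,
                                        min_area_km2, unit_subset=tr)[0]
                for div, tr in by_div.items()
            }
    if all(m in report.mare_by_model for m in al.MODELS):
        report.effectiveness = model_effectiveness(report.mare_by_model)
    return report
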