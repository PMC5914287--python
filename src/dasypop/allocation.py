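"""Dasymetric allocation: census counts to per-pixel population (models M1–M5).

Within each allocation zone Z — an (urban area ∩ county) or a county's
rural remainder — pixel k receives

    P_k = w0_k * w1_k**s * w2_k**d / sum_Z(w0 * w1**s * w2**d) * P_Z,

so zone totals are conserved exactly. The five models switch layers on
incrementally:

* M1 — county population spread homogeneously over the county (one zone).
* M2 — urban and rural zones separated, uniform within each.
* M3 — M2 restricted to inhabitable pixels (w0).
* M4 — M3 weighted by topographic suitability (w1**s).
* M5 — M4 weighted by socioeconomic desirability (w2**d).

The exponents s and d set the relative importance of topography and
desirability and are calibrated per division. Fractional persons are kept
(no rounding): conservation stays exact. A zone whose every pixel is
non-inhabitable falls back to uniform allocation over the whole zone —
conservation is treated as inviolable — with the fallback recorded in the
zone diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AllocationError, ConfigError
from .grids import ValueRaster
from .scaling import rural_population
from .study import Study

__all__ = ["ModelSpec", "AllocationResult", "allocate_zone", "run_model", "run_history"]

logger = logging.getLogger(__name__)

MODELS = ("M1", "M2", "M3", "M4", "M5")


@dataclass(frozen=True)
class ModelSpec:
    """Which model to run and its per-division exponents.

    ``s`` / ``d`` may be a scalar (applied everywhere) or a
    {division_id: value} mapping. M1–M3 ignore both; M4 ignores d.
    """

    model: str = "M5"
    s: "float | dict[int, float]" = 1.0
    d: "float | dict[int, float]" = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}; expected one of {MODELS}")

    def s_for(self, division: int) -> float:
        v = self.s.get(division, 1.0) if isinstance(self.s, dict) else self.s
        if v < 0:
            raise ConfigError(f"s must be >= 0, got {v}")
        return float(v)

    def d_for(self, division: int) -> float:
        v = self.d.get(division, 1.0) if isinstance(self.d, dict) else self.d
        if v < 0:
            raise ConfigError(f"d must be >= 0, got {v}")
        return float(v)


@dataclass
class AllocationResult:
    decade: int
    model: str
    population: ValueRaster
    #: per-zone records: zone, kind, P_Z, weight_sum, fallback
    diagnostics: list[dict] = field(default_factory=list)


def allocate_zone(
    p_z: float,
    w0: np.ndarray,
    w1: np.ndarray | None = None,
    w2: np.ndarray | None = None,
    s: float = 1.0,
    d: float = 1.0,
) -> tuple[np.ndarray, bool]:
    """Distribute ``p_z`` persons over one zone's pixels.

    Weight arrays are per-pixel over the zone; ``w1``/``w2`` default to 1.
    Returns (allocations, fallback_used). If the combined weight sums to
    zero the zone falls back to uniform allocation (population is never
    dropped).
    """
    w0 = np.asarray(w0, dtype=float)
    n = w0.size
    if n == 0:
        if p_z > 0:
            raise AllocationError(f"empty zone cannot receive {p_z} persons")
        return np.zeros(0), False
    if p_z < 0:
        raise AllocationError(f"zone population must be >= 0, got {p_z}")
    w = w0.copy()
    if w1 is not None:
        w = w * np.asarray(w1, dtype=float) ** s
    if w2 is not None:
        w = w * np.asarray(w2, dtype=float) ** d
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("zone of %d pixels has zero/invalid weight; uniform fallback", n)
        return np.full(n, p_z / n), True
    return p_z / total * w, False


def run_model(study: Study, spec: ModelSpec, decade: int) -> AllocationResult:
    """Allocate one decade's census counts under one model.

    Urban zones are (urban extent ∩ county) and receive that urban area's
    census population; each county's rural remainder receives
    P_R = P_T − Σ P_U. M1 skips the urban/rural split entirely.
    """
    grid = study.spec
    county = study.county_labels.labels
    county_pops = study.county_census.populations(decade)
    out = np.zeros(grid.shape)
    diagnostics: list[dict] = []
    model = spec.model

    need_w0 = model in ("M3", "M4", "M5")
    need_w1 = model in ("M4", "M5")
    need_w2 = model == "M5"
    w0 = study.ensure_w0().values if need_w0 else None
    w1 = study.ensure_w1().values if need_w1 else None
    w2 = study.w2_for(decade).values if need_w2 else None

    if model == "M1":
        for cid, p_t in county_pops.items():
            sel = county == cid
            if not sel.any():
                raise AllocationError(f"county {cid} absent from label raster (decade {decade})")
            vals, fb = allocate_zone(p_t, np.ones(int(sel.sum())))
            out[sel] = vals
            diagnostics.append(
                {"zone": f"county:{cid}", "kind": "county", "P_Z": p_t,
                 "weight_sum": float(sel.sum()), "fallback": fb}
            )
        return AllocationResult(decade, model, ValueRaster(grid, out), diagnostics)

    urban_labels = study.extent_raster(decade).labels
    for cid, p_t in county_pops.items():
        csel = county == cid
        if not csel.any():
            raise AllocationError(f"county {cid} absent from label raster (decade {decade})")
        div = study.division_of_county(cid)
        s_val = spec.s_for(div) if need_w1 else 1.0
        d_val = spec.d_for(div) if need_w2 else 1.0
        urb_here = urban_labels * csel
        urban_pop_sum = 0.0
        for uid in np.unique(urb_here[urb_here > 0]):
            uid = int(uid)
            ua = study.registry.areas.get(uid)
            if ua is None:
                raise ConfigError(f"extent carries urban id {uid} missing from registry")
            p_u = ua.population(decade)
            urban_pop_sum += p_u
            zsel = urb_here == uid
            idx = np.flatnonzero(zsel.ravel())
            vals, fb = _alloc(p_u, idx, w0, w1, w2, s_val, d_val)
            out.ravel()[idx] = vals
            diagnostics.append(
                {"zone": f"urban:{uid}/county:{cid}", "kind": "urban", "P_Z": p_u,
                 "weight_sum": float(len(idx)), "fallback": fb}
            )
        p_r = rural_population(p_t, [urban_pop_sum], county_id=cid, decade=decade)
        rsel = csel & (urban_labels == 0)
        idx = np.flatnonzero(rsel.ravel())
        if len(idx) == 0:
            if p_r > 0:
                raise AllocationError(
                    f"county {cid} has no rural pixels but rural population {p_r} (decade {decade})"
                )
        else:
            vals, fb = _alloc(p_r, idx, w0, w1, w2, s_val, d_val)
            out.ravel()[idx] = vals
            diagnostics.append(
                {"zone": f"rural:{cid}", "kind": "rural", "P_Z": p_r,
                 "weight_sum": float(len(idx)), "fallback": fb}
            )
    return AllocationResult(decade, model, ValueRaster(grid, out), diagnostics)


def _alloc(p_z, flat_idx, w0, w1, w2, s, d):
    z0 = w0.ravel()[flat_idx] if w0 is not None else np.ones(len(flat_idx))
    z1 = w1.ravel()[flat_idx] if w1 is not None else None
    z2 = w2.ravel()[flat_idx] if w2 is not None else None
    return allocate_zone(p_z, z0, z1, z2, s, d)


def run_history(
    study: Study,
    spec: ModelSpec,
    decades: "list[int] | None" = None,
    skip: "tuple[int, ...]" = (),
) -> dict[int, AllocationResult]:
    """One AllocationResult per decade, honoring a skip-list (e.g. a decade
    with no digital urban data)."""
    todo = [t for t in (decades or study.decades) if t not in skip]
    results: dict[int, AllocationResult] = {}
    for t in todo:
        try:
            results[t] = run_model(study, spec, t)
        except Exception as exc:
            raise type(exc)(f"decade {t}: {exc}") from exc
    return results
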