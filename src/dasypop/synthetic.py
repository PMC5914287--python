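"""Synthetic study regions with known ground truth.

The generator builds a complete fake study area satisfying the statistical
structure the downscaling framework assumes, so every stage can be tested
end-to-end without census downloads:

* counties tile the grid as rectangular blocks, grouped into vertical
  division strips; tracts and subdivisions partition counties;
* pixel elevation is county-mean elevation plus local texture, and county
  population density obeys ln(PD) = m*z + b + noise by construction;
* each sufficiently populous county holds one disc-shaped urban area whose
  footprint size follows A = alpha * P**beta with lognormal scatter, grown
  concentrically from the county center (so extent backprojection error is
  attributable to the algorithm, not geometry);
* populations follow exponential per-decade trajectories; urban areas drop
  out of the registry in decades where they fall below the 2500-person
  census threshold;
* per-decade ground-truth pixel populations are drawn from the full
  generative allocation model (M5 with the true scaling, topographic and
  desirability parameters), which makes parameter recovery well-posed.

All randomness flows through one seeded generator; runs are bit-identical
given the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allocation as al
from . import scaling as sc
from . import weights as wt
from .errors import ConfigError
from .extents import order_footprint
from .grids import CensusTable, GridSpec, LabelRaster, ValueRaster, zonal_sum
from .study import Study

__all__ = ["WorldConfig", "SyntheticWorld", "generate_world", "world_to_census"]


def _default_decades() -> list[int]:
    return list(range(1790, 2011, 10))


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults are the study conditions.

    ``true_beta_by_division`` / ``true_alpha_by_division`` /
    ``true_m_by_region`` accept a scalar (applied to every unit) or a
    {unit_id: value} mapping.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(90, 90))
    n_divisions: int = 3
    counties_per_division: int = 9
    tracts_per_county: int = 4
    subdivisions_per_county: int = 2
    decades: list[int] = field(default_factory=_default_decades)
    baseline_decade: int | None = None  # default: 2000 if present, else last decade

    # urban scaling law
    true_beta_by_division: "float | dict[int, float]" = 0.95
    true_alpha_by_division: "float | dict[int, float]" = 0.002
    scaling_noise_sd: float = 0.05  # sd of log10(area) scatter
    true_lambda_policy: "str | dict[int, float]" = "from_beta"

    # topography–density relation
    true_m_by_region: "float | dict[int, float]" = -0.0015
    base_log_density: float = 5.0  # ln(persons/km^2) at sea level
    density_noise_sd: float = 0.3
    elevation_range_m: float = 2000.0
    elevation_texture_sd_m: float = 25.0

    # demography
    urban_fraction: float = 0.4
    growth_rate: float = 1.3  # per-decade multiplicative growth
    growth_noise_sd: float = 0.05

    # landscape masks
    water_fraction: float = 0.05
    protected_fraction: float = 0.05

    # generative allocation exponents
    true_s: float = 1.0
    true_d: float = 0.6

    # optional low-population tracts (for inhabitability-cutoff experiments):
    # a fraction of non-urban tracts whose truth allocation weight is scaled
    # down, producing tracts that cutoff-less areal weighting overfills
    sparse_tract_fraction: float = 0.0
    sparse_tract_weight_factor: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.decades) != sorted(set(self.decades)):
            raise ConfigError("decades must be strictly increasing")
        for name in ("urban_fraction", "water_fraction", "protected_fraction",
                     "sparse_tract_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.growth_rate <= 0:
            raise ConfigError("growth_rate must be > 0")
        betas = (self.true_beta_by_division.values()
                 if isinstance(self.true_beta_by_division, dict)
                 else [self.true_beta_by_division])
        if any(b <= 0 for b in betas):
            raise ConfigError("true beta must be > 0")

    def beta(self, div: int) -> float:
        b = self.true_beta_by_division
        return b[div] if isinstance(b, dict) else b

    def alpha(self, div: int) -> float:
        a = self.true_alpha_by_division
        return a[div] if isinstance(a, dict) else a

    def m(self, region: int) -> float:
        m = self.true_m_by_region
        return m[region] if isinstance(m, dict) else m

    def lambda_(self, div: int) -> float:
        pol = self.true_lambda_policy
        if pol == "from_beta":
            return sc.lambda_from_beta(self.beta(div))
        if isinstance(pol, dict):
            return pol[div]
        raise ConfigError(f"unknown lambda policy {pol!r}")

    def resolve_baseline(self) -> int:
        if self.baseline_decade is not None:
            return self.baseline_decade
        return 2000 if 2000 in self.decades else max(self.decades)


@dataclass
class SyntheticWorld:
    """A generated study region with ground truth attached.

    ``study`` is the model-facing bundle (rasters + census tables, no
    fitted parameters); ``truth_by_decade`` holds the generative per-pixel
    population; the ``true_*`` fields are the parameters the truth was
    drawn with.
    """

    config: WorldConfig
    study: Study
    truth_by_decade: dict[int, ValueRaster]
    true_scaling_fits: dict[int, sc.ScalingFit]
    true_topo_fits: list[wt.RegionTopoFit]
    true_extent_series: list = field(default_factory=list)
    sparse_tract_ids: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# layout helpers


def _split_edges(n_cells: int, n_parts: int) -> np.ndarray:
    return np.linspace(0, n_cells, n_parts + 1).round().astype(int)


def _factor_pair(n: int) -> tuple[int, int]:
    """(rows, cols) with rows*cols == n, as square as possible."""
    best = (1, n)
    for a in range(1, int(math.isqrt(n)) + 1):
        if n % a == 0:
            best = (a, n // a)
    return best


def _tile(labels: np.ndarray, r0: int, r1: int, c0: int, c1: int,
          n_parts: int, start_id: int) -> int:
    """Label an n_parts rectangular partition of a block; returns next id."""
    nr, nc = _factor_pair(n_parts)
    redges = r0 + _split_edges(r1 - r0, nr)
    cedges = c0 + _split_edges(c1 - c0, nc)
    uid = start_id
    for i in range(nr):
        for j in range(nc):
            labels[redges[i]:redges[i + 1], cedges[j]:cedges[j + 1]] = uid
            uid += 1
    return uid


# ---------------------------------------------------------------------------
# generation


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build a :class:`SyntheticWorld` from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    spec = config.grid
    nrows, ncols = spec.shape
    cell = spec.cell_area_km2
    baseline = config.resolve_baseline()
    if baseline not in config.decades:
        raise ConfigError(f"baseline decade {baseline} not in decade list")

    # --- administrative partitions ---------------------------------------
    division = np.zeros(spec.shape, dtype=np.int64)
    county = np.zeros_like(division)
    tract = np.zeros_like(division)
    subdiv = np.zeros_like(division)
    div_cols = _split_edges(ncols, config.n_divisions)
    county_blocks: dict[int, tuple[int, int, int, int]] = {}
    cid = tid = sid = 1
    for d in range(config.n_divisions):
        c0, c1 = div_cols[d], div_cols[d + 1]
        division[:, c0:c1] = d + 1
        nr, nc = _factor_pair(config.counties_per_division)
        redges = _split_edges(nrows, nr)
        cedges = c0 + _split_edges(c1 - c0, nc)
        for i in range(nr):
            for j in range(nc):
                blk = (redges[i], redges[i + 1], cedges[j], cedges[j + 1])
                county[blk[0]:blk[1], blk[2]:blk[3]] = cid
                county_blocks[cid] = blk
                tid = _tile(tract, *blk, config.tracts_per_county, tid)
                sid = _tile(subdiv, *blk, config.subdivisions_per_county, sid)
                cid += 1
    region = division.copy()  # one region per division by default

    county_ids = sorted(county_blocks)
    division_of = {c: int(division[county_blocks[c][0], county_blocks[c][2]])
                   for c in county_ids}

    # --- elevation --------------------------------------------------------
    # county means are stratified over the elevation range within each
    # division: every division keeps low-elevation (populous, urban-bearing)
    # counties, so per-division scaling fits are always identifiable
    county_mean_z: dict[int, float] = {}
    for d in range(1, config.n_divisions + 1):
        cs = [c for c in county_ids if division_of[c] == d]
        strata = rng.permutation(len(cs))
        for c, k in zip(cs, strata):
            county_mean_z[c] = (
                (k + rng.uniform(0.1, 0.9)) / len(cs) * config.elevation_range_m
            )
    elevation = np.empty(spec.shape)
    for c in county_ids:
        selc = county == c
        elevation[selc] = county_mean_z[c] + rng.normal(
            0.0, config.elevation_texture_sd_m, int(selc.sum())
        )
    elevation = np.clip(elevation, 0.0, None)

    # --- landscape masks (avoid a reserved central disc per county) ------
    reserved = np.zeros(spec.shape, dtype=bool)
    centers: dict[int, tuple[int, int]] = {}
    r_reserve: dict[int, float] = {}
    rows_idx, cols_idx = np.indices(spec.shape)
    for c in county_ids:
        r0, r1, c0, c1 = county_blocks[c]
        ctr = ((r0 + r1 - 1) // 2, (c0 + c1 - 1) // 2)
        centers[c] = ctr
        r_reserve[c] = 0.45 * min(r1 - r0, c1 - c0)
        d = np.hypot(rows_idx - ctr[0], cols_idx - ctr[1])
        reserved |= (county == c) & (d <= r_reserve[c])

    def _patches(fraction: float, forbidden: np.ndarray) -> np.ndarray:
        mask = np.zeros(spec.shape, dtype=bool)
        target = int(fraction * spec.n_rows * spec.n_cols)
        attempts = 0
        while mask.sum() < target and attempts < 50 * max(target, 1):
            attempts += 1
            rr = rng.integers(0, nrows)
            cc = rng.integers(0, ncols)
            rad = rng.integers(1, 3)
            patch = (np.hypot(rows_idx - rr, cols_idx - cc) <= rad) & ~forbidden & ~mask
            mask |= patch
        return mask

    water = _patches(config.water_fraction, reserved)
    protected = _patches(config.protected_fraction, reserved | water)

    # --- county baseline populations from the topo-density relation ------
    uninhab = water | protected | (elevation > 3500.0)
    county_pop_base: dict[int, float] = {}
    for c in county_ids:
        selc = county == c
        a_inhab = float((selc & ~uninhab).sum()) * cell
        z = county_mean_z[c]
        ln_pd = (config.m(division_of[c]) * z + config.base_log_density
                 + rng.normal(0.0, config.density_noise_sd))
        county_pop_base[c] = math.exp(ln_pd) * max(a_inhab, cell)

    # --- urban areas ------------------------------------------------------
    registry = sc.UrbanRegistry()
    decades = list(config.decades)
    j_base = decades.index(baseline)
    growth = {c: config.growth_rate * math.exp(rng.normal(0.0, config.growth_noise_sd))
              for c in county_ids}
    county_pops: dict[int, dict[int, float]] = {
        c: {t: county_pop_base[c] * growth[c] ** (j - j_base)
            for j, t in enumerate(decades)}
        for c in county_ids
    }

    uid = 1
    for c in county_ids:
        p_u_base = config.urban_fraction * county_pop_base[c]
        if p_u_base < sc.URBAN_POPULATION_THRESHOLD:
            continue
        div = division_of[c]
        area = (config.alpha(div) * p_u_base ** config.beta(div)
                * 10.0 ** rng.normal(0.0, config.scaling_noise_sd))
        n_pix = max(int(round(area / cell)), 1)
        capacity = int(math.pi * r_reserve[c] ** 2)
        if n_pix > capacity:
            raise ConfigError(
                f"county {c}: urban footprint of {n_pix} pixels does not fit the "
                f"county (capacity {capacity}); lower urban_fraction or enlarge the grid"
            )
        selc_px = np.argwhere(county == c)
        ordered = order_footprint(selc_px, centers[c])
        footprint = ordered[:n_pix]
        pops = {t: config.urban_fraction * county_pops[c][t] for t in decades}
        pops = {t: p for t, p in pops.items() if p >= sc.URBAN_POPULATION_THRESHOLD}
        registry.add(
            sc.UrbanArea(
                urban_id=uid, division_id=div, county_id=c,
                population_by_decade=pops, footprint=footprint, center=centers[c],
                area_km2=area,
            )
        )
        uid += 1

    # --- census tables ----------------------------------------------------
    county_rows = [
        {"unit_id": c, "decade": t, "population": county_pops[c][t],
         "area_km2": float((county == c).sum()) * cell}
        for c in county_ids for t in decades
    ]
    county_census = CensusTable(pd.DataFrame(county_rows))

    spec_rasters = dict(
        county_labels=LabelRaster(spec, county, "county"),
        division_labels=LabelRaster(spec, division, "division"),
        region_labels=LabelRaster(spec, region, "region"),
        tract_labels=LabelRaster(spec, tract, "tract"),
        subdivision_labels=LabelRaster(spec, subdiv, "subdivision"),
        elevation=ValueRaster(spec, elevation),
    )

    # --- ground truth: the generative model with true parameters ---------
    true_scaling = {
        int(d): sc.ScalingFit(int(d), config.alpha(int(d)), config.beta(int(d)),
                              config.lambda_(int(d)), n_fit=3, r_squared=1.0)
        for d in np.unique(division[division > 0])
    }
    true_topo = [
        wt.RegionTopoFit(region_id=int(r), slope=config.m(int(r)),
                         intercept=config.base_log_density, n_fit=3,
                         p_value=0.0, r_squared=1.0)
        for r in np.unique(region[region > 0])
    ]
    schedule = wt.TravelRangeSchedule(anchors={decades[0]: 30.0, baseline: 100.0})
    truth_study = Study(
        spec=spec, **spec_rasters,
        county_census=county_census, registry=registry,
        decades=decades, baseline_decade=baseline,
        water_mask=water, protected_mask=protected,
        travel_schedule=schedule,
        scaling_fits=true_scaling, topo_fits=true_topo,
    )

    sparse_ids: list[int] = []
    if config.sparse_tract_fraction > 0:
        urban_px = np.zeros(spec.shape, dtype=bool)
        for ua in registry:
            urban_px[ua.footprint[:, 0], ua.footprint[:, 1]] = True
        candidates = [int(t) for t in np.unique(tract[tract > 0])
                      if not urban_px[tract == t].any()]
        k = int(round(config.sparse_tract_fraction * len(candidates)))
        sparse_ids = sorted(rng.choice(candidates, size=k, replace=False).tolist())
        # scale the truth's suitability down inside sparse tracts so a
        # cutoff-less areal model overfills them
        w1 = truth_study.ensure_w1().values.copy()
        sparse_sel = np.isin(tract, sparse_ids)
        w1[sparse_sel] *= config.sparse_tract_weight_factor
        truth_study._w1 = ValueRaster(spec, w1)

    truth_spec = al.ModelSpec("M5", s=config.true_s, d=config.true_d)
    truth = {t: al.run_model(truth_study, truth_spec, t).population for t in decades}

    # --- reference tables from truth (tracts / subdivisions) -------------
    tract_rows, subdiv_rows = [], []
    for t in decades:
        for zid, v in zonal_sum(truth[t], spec_rasters["tract_labels"]).items():
            tract_rows.append({"unit_id": zid, "decade": t, "population": v,
                               "area_km2": float((tract == zid).sum()) * cell})
        for zid, v in zonal_sum(truth[t], spec_rasters["subdivision_labels"]).items():
            subdiv_rows.append({"unit_id": zid, "decade": t, "population": v,
                                "area_km2": float((subdiv == zid).sum()) * cell})

    study = Study(
        spec=spec, **spec_rasters,
        county_census=county_census, registry=registry,
        decades=decades, baseline_decade=baseline,
        tract_census=CensusTable(pd.DataFrame(tract_rows)),
        subdivision_census=CensusTable(pd.DataFrame(subdiv_rows)),
        water_mask=water, protected_mask=protected,
        travel_schedule=schedule,
    )
    return SyntheticWorld(
        config=config, study=study, truth_by_decade=truth,
        true_scaling_fits=true_scaling, true_topo_fits=true_topo,
        true_extent_series=truth_study.ensure_extents(),
        sparse_tract_ids=sparse_ids,
    )


def world_to_census(world: SyntheticWorld) -> dict[str, pd.DataFrame]:
    """Recompute the demographic ledger by aggregating the truth rasters.

    Returns county / urban / tract / subdivision long tables. County totals
    equal the generative census by conservation; per-urban populations are
    sums over each decade's true extent.
    """
    study = world.study
    out: dict[str, list[dict]] = {"county": [], "urban": [], "tract": [], "subdivision": []}
    for t, truth in world.truth_by_decade.items():
        for zid, v in zonal_sum(truth, study.county_labels).items():
            out["county"].append({"unit_id": zid, "decade": t, "population": v})
        for zid, v in zonal_sum(truth, study.tract_labels).items():
            out["tract"].append({"unit_id": zid, "decade": t, "population": v})
        for zid, v in zonal_sum(truth, study.subdivision_labels).items():
            out["subdivision"].append({"unit_id": zid, "decade": t, "population": v})
        # per-urban sums over the decade's true extent
        for ua in study.registry.existing_in(t):
            fits = world.true_scaling_fits[ua.division_id]
            cellarea = study.spec.cell_area_km2
            if t == study.baseline_decade:
                n_t = len(ua.footprint)
            else:
                n_t = min(max(int(round(
                    sc.predict_area(ua.population(t), fits) / cellarea)), 1),
                    len(ua.footprint))
            px = order_footprint(ua.footprint, ua.center)[:n_t]
            out["urban"].append({
                "unit_id": ua.urban_id, "decade": t, "county_id": ua.county_id,
                "population": float(truth.values[px[:, 0], px[:, 1]].sum()),
            })
    return {k: pd.DataFrame(v) for k, v in out.items()}
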