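"""Influence-coefficient grids: inhabitability (w0), topography (w1),
socioeconomic desirability (w2).

w0 is a static binary mask excluding protected land, waterbodies of at
least 1 km², elevation above 3500 m, and pixels in census tracts below a
per-division population cutoff (areal weighting systematically overfills
low-population tracts; masking them out lowers overall error).

w1 = exp(m_mu * z_k) comes from a per-region OLS of ln county population
density on county mean elevation; a region whose slope is not significant
(p >= 0.05) is left unweighted (w1 = 1), the treatment the original study
applied to Colorado. Density is computed over inhabitable area only.
Optional elevation bands allow sub-region fits.

w2 differs between urban and rural pixels. Urban pixels decay with radial
distance from their urban center as r**(-lambda) with lambda = 2 - 2*beta.
Rural pixels carry a gravity-model market potential: the P/r²-weighted
mean population of urban areas within the decade's travel range D_t, which
grows log-linearly from 30 km (first decade) to 100 km (baseline) as
transport technology improves. Rural pixels with no urban area in range get
the neutral weight 1, so allocation there degrades gracefully to w0*w1
instead of zeroing out remote counties. Distances are clamped below at half
a cell to avoid the r -> 0 singularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import ConfigError, FitError
from .grids import GridSpec, LabelRaster, ValueRaster

__all__ = [
    "InhabitabilityConfig",
    "inhabitability_mask",
    "RegionTopoFit",
    "fit_topo_relation",
    "topo_weight",
    "urban_distance_weight",
    "TravelRangeSchedule",
    "travel_range",
    "market_potential",
    "WeightStack",
    "normalize_by_division",
]


# ---------------------------------------------------------------------------
# w0 — inhabitability


@dataclass
class InhabitabilityConfig:
    elevation_max_m: float = 3500.0
    min_water_patch_km2: float = 1.0
    #: per-division tract-population cutoff; tracts below it are masked out
    cutoff_population_by_division: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.elevation_max_m <= 0 or self.min_water_patch_km2 <= 0:
            raise ConfigError("inhabitability thresholds must be positive")


def _large_water_patches(water_mask: np.ndarray, min_km2: float, cell_area: float) -> np.ndarray:
    """Water pixels belonging to 4-connected patches of at least min_km2."""
    lab, n = ndimage.label(water_mask)
    if n == 0:
        return np.zeros_like(water_mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    min_pixels = min_km2 / cell_area
    big = np.zeros(n + 1, dtype=bool)
    big[1:] = sizes[1:] * cell_area >= min_km2 - 1e-12 if min_pixels > 1 else sizes[1:] > 0
    return big[lab]


def inhabitability_mask(
    elevation: ValueRaster,
    water_mask: np.ndarray | None = None,
    protected_mask: np.ndarray | None = None,
    tract_labels: LabelRaster | None = None,
    tract_populations: dict[int, float] | None = None,
    division_labels: LabelRaster | None = None,
    config: InhabitabilityConfig | None = None,
) -> ValueRaster:
    """Binary w0 raster: 1 inhabitable, 0 excluded. Constant across decades.

    A pixel is excluded if protected, in a water patch of at least
    ``min_water_patch_km2``, above ``elevation_max_m``, or in a tract whose
    population at the calibration decade is below its division's cutoff.
    """
    cfg = config or InhabitabilityConfig()
    spec = elevation.spec
    w0 = np.ones(spec.shape)
    z = elevation.values
    w0[np.isfinite(z) & (z > cfg.elevation_max_m)] = 0.0
    if protected_mask is not None:
        w0[np.asarray(protected_mask, dtype=bool)] = 0.0
    if water_mask is not None:
        big = _large_water_patches(
            np.asarray(water_mask, dtype=bool), cfg.min_water_patch_km2, spec.cell_area_km2
        )
        w0[big] = 0.0
    if cfg.cutoff_population_by_division and tract_labels is not None:
        if tract_populations is None or division_labels is None:
            raise ConfigError("tract cutoffs require tract populations and division labels")
        for tract_id, pop in tract_populations.items():
            px = tract_labels.labels == tract_id
            if not px.any():
                continue
            div = int(division_labels.labels[px][0])
            cutoff = cfg.cutoff_population_by_division.get(div)
            if cutoff is not None and pop < cutoff:
                w0[px] = 0.0
    w0[~np.isfinite(z)] = 0.0
    return ValueRaster(spec, w0)


# ---------------------------------------------------------------------------
# w1 — topographic suitability


@dataclass(frozen=True)
class RegionTopoFit:
    """ln(density) ~ elevation regression for one region (or elevation band)."""

    region_id: int
    slope: float  # 1/m
    intercept: float  # ln(persons/km^2) at z = 0
    n_fit: int
    p_value: float
    r_squared: float
    elevation_band: tuple[float, float] | None = None
    #: False when the slope is not significant — the region goes unweighted
    weighted: bool = True


def fit_topo_relation(
    densities: "np.ndarray | list[float]",
    mean_elevations: "np.ndarray | list[float]",
    region_id: int = 0,
    elevation_band: tuple[float, float] | None = None,
    significance: float = 0.05,
) -> RegionTopoFit:
    """OLS of ln county density on county mean elevation for one region.

    Counties outside ``elevation_band`` (if given) are dropped before
    fitting. ``weighted`` is False when the slope fails the significance
    gate, in which case :func:`topo_weight` passes w1 = 1 through.
    """
    pd_ = np.asarray(densities, dtype=float)
    z = np.asarray(mean_elevations, dtype=float)
    if elevation_band is not None:
        lo, hi = elevation_band
        keep = (z >= lo) & (z < hi)
        pd_, z = pd_[keep], z[keep]
    if len(pd_) < 3:
        raise FitError(f"region {region_id}: need >= 3 counties, got {len(pd_)}")
    if np.any(pd_ <= 0):
        raise FitError(f"region {region_id}: densities must be > 0")
    if np.ptp(z) == 0:
        raise FitError(f"region {region_id}: zero variance in elevation")
    res = stats.linregress(z, np.log(pd_))
    return RegionTopoFit(
        region_id=region_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_fit=len(pd_),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        elevation_band=elevation_band,
        weighted=bool(res.pvalue < significance),
    )


def topo_weight(
    elevation: ValueRaster,
    fits: "list[RegionTopoFit] | RegionTopoFit",
    region_labels: LabelRaster | None = None,
) -> ValueRaster:
    """w1 = exp(m_mu * z_k) per region; 1 where the region is unweighted.

    Steady over time. Multiple fits for one region (elevation bands) are
    applied to the pixels whose elevation falls in each band.
    """
    if isinstance(fits, RegionTopoFit):
        fits = [fits]
    spec = elevation.spec
    z = elevation.values
    w1 = np.ones(spec.shape)
    for fit in fits:
        if region_labels is not None:
            sel = region_labels.labels == fit.region_id
        else:
            sel = np.ones(spec.shape, dtype=bool)
        if fit.elevation_band is not None:
            lo, hi = fit.elevation_band
            sel = sel & np.isfinite(z) & (z >= lo) & (z < hi)
        else:
            sel = sel & np.isfinite(z)
        if fit.weighted:
            w1[sel] = np.exp(fit.slope * z[sel])
    return ValueRaster(spec, w1)


# ---------------------------------------------------------------------------
# w2 — socioeconomic desirability


def _r_min(cell_size_km: float) -> float:
    return cell_size_km / 2.0


def urban_distance_weight(
    pixels: np.ndarray,
    center: tuple[int, int],
    lambda_: float,
    cell_size_km: float = 1.0,
) -> np.ndarray:
    """Inverse-power density gradient on urban pixels: w2 = r**(-lambda).

    ``pixels`` are (row, col) coordinates of the urban extent; distances are
    center-to-center in km and clamped below at half a cell. lambda = 0
    gives a flat profile.
    """
    px = np.asarray(pixels)
    if not np.isfinite(lambda_):
        raise ValueError("lambda_ must be finite")
    if lambda_ == 0:
        return np.ones(len(px))
    r = np.hypot(px[:, 0] - center[0], px[:, 1] - center[1]) * cell_size_km
    r = np.maximum(r, _r_min(cell_size_km))
    return r**(-lambda_)


@dataclass
class TravelRangeSchedule:
    """Daily per-capita travel range D_t, anchored and log-linear in time.

    Defaults: 30 km at 1790 rising to 100 km at 2000. Outside the anchor
    span the range is clamped at the nearest anchor.
    """

    anchors: dict[int, float] = field(default_factory=lambda: {1790: 30.0, 2000: 100.0})

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ConfigError("travel-range schedule needs at least one anchor")
        if any(v <= 0 for v in self.anchors.values()):
            raise ConfigError("travel-range anchors must be positive")
        years = sorted(self.anchors)
        vals = [self.anchors[y] for y in years]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ConfigError("travel range must be nondecreasing over decades")

    def range_km(self, t: int) -> float:
        years = sorted(self.anchors)
        if t <= years[0]:
            return self.anchors[years[0]]
        if t >= years[-1]:
            return self.anchors[years[-1]]
        for y0, y1 in zip(years, years[1:]):
            if y0 <= t <= y1:
                f = (t - y0) / (y1 - y0)
                return float(math.exp((1 - f) * math.log(self.anchors[y0])
                                      + f * math.log(self.anchors[y1])))
        raise AssertionError("unreachable")


def travel_range(t: int, schedule: TravelRangeSchedule | None = None) -> float:
    """D_t in km for decade ``t`` (default 30 km in 1790 -> 100 km in 2000)."""
    return (schedule or TravelRangeSchedule()).range_km(t)


def market_potential(
    pixels: np.ndarray,
    urban_centers: np.ndarray,
    urban_populations: np.ndarray,
    d_t_km: float,
    cell_size_km: float = 1.0,
) -> np.ndarray:
    """Gravity-model market potential for rural pixels.

    w2_k = [sum_phi P_phi / r_k,phi^2] / [sum_phi 1 / r_k,phi^2] over urban
    areas within the travel range d_t_km — an inverse-square-weighted mean
    of in-range urban populations, so each value lies between the smallest
    and largest in-range population. Pixels with no urban area in range get
    the neutral weight 1.
    """
    px = np.asarray(pixels, dtype=float)
    out = np.ones(len(px))
    centers = np.asarray(urban_centers, dtype=float)
    pops = np.asarray(urban_populations, dtype=float)
    if len(centers) == 0 or len(px) == 0:
        return out
    # (n_pixels, n_urban) distance matrix in km
    r = np.hypot(
        px[:, None, 0] - centers[None, :, 0], px[:, None, 1] - centers[None, :, 1]
    ) * cell_size_km
    in_range = r <= d_t_km
    r = np.maximum(r, _r_min(cell_size_km))
    inv_r2 = np.where(in_range, 1.0 / r**2, 0.0)
    denom = inv_r2.sum(axis=1)
    numer = (inv_r2 * pops[None, :]).sum(axis=1)
    has = denom > 0
    out[has] = numer[has] / denom[has]
    # one in-range source: the distance cancels algebraically, so return
    # its population exactly rather than through the quotient
    single = in_range.sum(axis=1) == 1
    if single.any():
        out[single] = pops[np.argmax(in_range[single], axis=1)]
    return out


# ---------------------------------------------------------------------------
# stack assembly


@dataclass
class WeightStack:
    """The three influence-coefficient rasters for one decade."""

    decade: int
    w0: ValueRaster
    w1: ValueRaster
    w2: ValueRaster
    provenance: dict = field(default_factory=dict)


def normalize_by_division(weight: ValueRaster, division_labels: LabelRaster) -> ValueRaster:
    """Max-normalize a weight layer to 1 within each division.

    Cosmetic for allocation (every allocation zone sits inside one
    division, and zone-constant rescaling cancels in the normalized
    product) but matches the published convention of weights in [0, 1].
    """
    out = weight.values.copy()
    for div in division_labels.ids():
        sel = division_labels.labels == div
        mx = np.nanmax(out[sel]) if sel.any() else 0.0
        if mx > 0:
            out[sel] = out[sel] / mx
    return ValueRaster(weight.spec, out)
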