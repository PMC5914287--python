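"""Urban area–population scaling law and county rural bookkeeping.

The footprint of an urban area scales with its population as a power law,

    A_U = alpha_delta * P_U ** beta_delta

fitted per census division delta by OLS of log10(A_U) on log10(P_U) at the
baseline decade (the newest decade with full urban-footprint coverage). The
fitted exponent also fixes the within-urban density gradient

    lambda_delta = 2 - 2 * beta_delta,

the exponent of the inverse-power decay of urban population density with
distance from the urban center. Scaling parameters are treated as constant
over decades.

Rural population and area per county are the book-keeping differences
P_R = P_T - sum(P_U) and A_R = A_T - sum(A_U); a negative difference means
the census tables disagree and raises :class:`DataInconsistencyError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataInconsistencyError, FitError

__all__ = [
    "ScalingFit",
    "UrbanArea",
    "UrbanRegistry",
    "fit_area_population_scaling",
    "predict_area",
    "lambda_from_beta",
    "rural_population",
    "rural_area",
]

URBAN_POPULATION_THRESHOLD = 2500  # census definition of an urban area


def lambda_from_beta(beta: float) -> float:
    """Density-gradient exponent implied by the area–population exponent."""
    return 2.0 - 2.0 * beta


@dataclass(frozen=True)
class ScalingFit:
    """Per-division power-law fit A = alpha * P**beta with derived gradient."""

    division_id: int
    alpha: float  # km^2 * persons^-beta
    beta: float
    lambda_: float
    n_fit: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise FitError(f"division {self.division_id}: alpha must be > 0")
        if self.n_fit < 3:
            raise FitError(f"division {self.division_id}: need >= 3 areas, got {self.n_fit}")


def fit_area_population_scaling(
    areas_km2: "np.ndarray | list[float]",
    populations: "np.ndarray | list[float]",
    division_id: int = 0,
) -> ScalingFit:
    """OLS of log10 area on log10 population for one census division.

    The regression direction follows the prediction direction (area from
    population). Any log base gives the same exponent; the intercept is
    converted to alpha = 10**intercept.
    """
    A = np.asarray(areas_km2, dtype=float)
    P = np.asarray(populations, dtype=float)
    if A.shape != P.shape:
        raise FitError(f"division {division_id}: area/population length mismatch")
    if len(A) < 3:
        raise FitError(f"division {division_id}: need >= 3 urban areas, got {len(A)}")
    if np.any(A <= 0) or np.any(P <= 0):
        raise FitError(f"division {division_id}: areas and populations must be > 0")
    logP = np.log10(P)
    if np.ptp(logP) == 0:
        raise FitError(f"division {division_id}: zero variance in log population")
    res = stats.linregress(logP, np.log10(A))
    beta = float(res.slope)
    return ScalingFit(
        division_id=division_id,
        alpha=float(10.0**res.intercept),
        beta=beta,
        lambda_=lambda_from_beta(beta),
        n_fit=len(A),
        r_squared=float(res.rvalue**2),
    )


def predict_area(population: float, fit: ScalingFit) -> float:
    """Footprint area in km² implied by the scaling law for one urban area."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return fit.alpha * population**fit.beta


def rural_population(total: float, urban_populations: "list[float]",
                     county_id: int | None = None, decade: int | None = None) -> float:
    """County rural population P_R = P_T - sum of urban populations."""
    if total < 0 or any(p < 0 for p in urban_populations):
        raise ValueError("populations must be >= 0")
    rural = total - float(np.sum(urban_populations)) if urban_populations else total
    if rural < 0:
        raise DataInconsistencyError(
            f"urban population exceeds county total "
            f"(county={county_id}, decade={decade}): {total} < {total - rural}"
        )
    return rural


def rural_area(total_km2: float, urban_areas_km2: "list[float]",
               county_id: int | None = None) -> float:
    """County rural area A_R = A_T - sum of urban footprints."""
    if total_km2 < 0 or any(a < 0 for a in urban_areas_km2):
        raise ValueError("areas must be >= 0")
    rural = total_km2 - float(np.sum(urban_areas_km2)) if urban_areas_km2 else total_km2
    if rural < 0:
        raise DataInconsistencyError(
            f"urban area exceeds county total area (county={county_id})"
        )
    return rural


@dataclass
class UrbanArea:
    """One urban area: census populations over decades plus baseline footprint.

    ``footprint`` is an (n, 2) array of (row, col) pixels at the baseline
    decade, forming one contiguous component inside a single county;
    ``center`` is a (row, col) pixel coordinate. ``area_km2`` is the census
    areal extent at the baseline decade — a continuous value, finer than
    the whole-pixel footprint — used for scaling fits when available.
    """

    urban_id: int
    division_id: int
    county_id: int
    population_by_decade: dict[int, float]
    footprint: np.ndarray | None = None
    center: tuple[int, int] | None = None
    area_km2: float | None = None

    def exists_in(self, decade: int) -> bool:
        return self.population_by_decade.get(decade, 0.0) >= URBAN_POPULATION_THRESHOLD

    def population(self, decade: int) -> float:
        return self.population_by_decade.get(decade, 0.0)


@dataclass
class UrbanRegistry:
    """All urban areas of a study region, keyed by urban id."""

    areas: dict[int, UrbanArea] = field(default_factory=dict)

    def add(self, area: UrbanArea) -> None:
        self.areas[area.urban_id] = area

    def __len__(self) -> int:
        return len(self.areas)

    def __iter__(self):
        return iter(self.areas.values())

    def existing_in(self, decade: int) -> "list[UrbanArea]":
        return [a for a in self.areas.values() if a.exists_in(decade)]

    def in_county(self, county_id: int) -> "list[UrbanArea]":
        return [a for a in self.areas.values() if a.county_id == county_id]

    def in_division(self, division_id: int) -> "list[UrbanArea]":
        return [a for a in self.areas.values() if a.division_id == division_id]
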