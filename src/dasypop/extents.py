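"""Historical urban-extent reconstruction by concentric shrinking.

Footprints are fully observed only at the baseline decade. Earlier extents
are reconstructed under two assumptions: urbanization is monotonic (an area
once urban stays urban), and urban areas grew outward from their center.
The baseline footprint pixels are sorted by distance to the center; the
extent in decade t is the prefix of that ordering whose pixel count matches
the scaling-law area A_U,t — so extents are nested across decades by
construction.

Ties in the distance sort are broken by (distance, angle from east, row,
column), giving a total order and platform-independent output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, LabelRaster

__all__ = [
    "urban_center",
    "order_footprint",
    "UrbanExtentSeries",
    "delineate_history",
    "overlap_fraction",
    "extent_label_raster",
]


def urban_center(footprint: np.ndarray) -> tuple[int, int]:
    """Footprint pixel nearest the (unweighted) centroid of the footprint.

    Ties go to the smallest row, then smallest column. The centroid itself
    may fall outside a non-convex footprint; snapping keeps the center on
    urban land.
    """
    fp = np.asarray(footprint)
    if fp.size == 0:
        raise ValueError("empty footprint has no center")
    centroid = fp.mean(axis=0)
    d2 = ((fp - centroid) ** 2).sum(axis=1)
    order = np.lexsort((fp[:, 1], fp[:, 0], d2))
    r, c = fp[order[0]]
    return int(r), int(c)


def order_footprint(footprint: np.ndarray, center: tuple[int, int]) -> np.ndarray:
    """Footprint pixels sorted by (distance to center, angle from east, row, col)."""
    fp = np.asarray(footprint)
    dr = fp[:, 0] - center[0]
    dc = fp[:, 1] - center[1]
    dist = np.hypot(dr, dc)
    # screen coordinates: angle measured from east, counterclockwise in map terms
    ang = np.mod(np.arctan2(-dr, dc), 2 * math.pi)
    order = np.lexsort((fp[:, 1], fp[:, 0], ang, dist))
    return fp[order]


@dataclass
class UrbanExtentSeries:
    """Per-decade reconstructed extent of one urban area.

    ``ordered_pixels`` is the distance-sorted baseline footprint;
    ``n_by_decade`` maps each decade the area exists to the prefix length
    (pixel count) of its extent.
    """

    urban_id: int
    center: tuple[int, int]
    ordered_pixels: np.ndarray
    n_by_decade: dict[int, int] = field(default_factory=dict)
    clamped_decades: list[int] = field(default_factory=list)

    def exists_in(self, decade: int) -> bool:
        return decade in self.n_by_decade

    def extent_pixels(self, decade: int) -> np.ndarray:
        """(n, 2) array of (row, col) pixels urban in ``decade``."""
        if decade not in self.n_by_decade:
            return np.empty((0, 2), dtype=int)
        return self.ordered_pixels[: self.n_by_decade[decade]]


def delineate_history(
    footprint: np.ndarray,
    target_areas_km2: dict[int, float],
    cell_area_km2: float = 1.0,
    center: tuple[int, int] | None = None,
    urban_id: int = 0,
) -> UrbanExtentSeries:
    """Backproject per-decade extents from a baseline footprint.

    Parameters
    ----------
    footprint
        (n, 2) baseline-decade footprint pixels.
    target_areas_km2
        Scaling-law area for every decade the urban area exists. Targets
        exceeding the baseline footprint are clamped to the full footprint
        (backprojection should shrink, not grow); clamped decades are
        recorded on the series. The minimum extent is one pixel: an
        existing urban area cannot have an empty footprint.
    """
    fp = np.asarray(footprint)
    if fp.size == 0:
        raise ValueError("empty footprint")
    if center is None:
        center = urban_center(fp)
    ordered = order_footprint(fp, center)
    series = UrbanExtentSeries(urban_id=urban_id, center=center, ordered_pixels=ordered)
    n_max = len(ordered)
    for decade, area in target_areas_km2.items():
        if area <= 0:
            raise ValueError(f"decade {decade}: target area must be > 0, got {area}")
        n_t = int(round(area / cell_area_km2))
        if n_t > n_max:
            series.clamped_decades.append(decade)
        series.n_by_decade[decade] = min(max(n_t, 1), n_max)
    return series


def overlap_fraction(model_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """|model AND reference| / |reference| for two aligned binary masks.

    The fraction of reference urban pixels that the reconstruction covers.
    An empty reference leaves the score undefined (NaN).
    """
    m = np.asarray(model_mask, dtype=bool)
    r = np.asarray(reference_mask, dtype=bool)
    if m.shape != r.shape:
        raise ValueError(f"mask shapes differ: {m.shape} vs {r.shape}")
    n_ref = int(r.sum())
    if n_ref == 0:
        return float("nan")
    return float((m & r).sum() / n_ref)


def extent_label_raster(
    series_list: "list[UrbanExtentSeries]", decade: int, spec: GridSpec
) -> LabelRaster:
    """Urban-id label raster for one decade (0 = not urban)."""
    labels = np.zeros(spec.shape, dtype=np.int64)
    for s in series_list:
        px = s.extent_pixels(decade)
        if len(px):
            labels[px[:, 0], px[:, 1]] = s.urban_id
    return LabelRaster(spec, labels, level="urban")
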