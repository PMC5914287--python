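"""Study bundle: everything the allocation models need for one region.

A :class:`Study` collects the aligned raster stack (county / division /
region / tract labels, elevation, masks), the census ledger (county totals
plus per-urban-area populations with baseline footprints), and lazily
derives the fitted pieces downstream stages share:

* per-division area–population scaling fits (from the baseline decade),
* per-region ln(density)–elevation fits,
* backprojected urban-extent series,
* the w0 / w1 / per-decade w2 weight rasters.

Each derived piece can also be injected directly (``scaling_fits=...``),
which is how the synthetic generator runs the generative model with the
true parameters instead of fitted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import extents as ext
from . import scaling as sc
from . import weights as wt
from .errors import ConfigError
from .grids import CensusTable, GridSpec, LabelRaster, ValueRaster, zonal_mean

__all__ = ["Study"]


@dataclass
class Study:
    spec: GridSpec
    county_labels: LabelRaster
    division_labels: LabelRaster
    region_labels: LabelRaster
    elevation: ValueRaster
    county_census: CensusTable
    registry: sc.UrbanRegistry
    decades: list[int]
    baseline_decade: int
    tract_labels: LabelRaster | None = None
    subdivision_labels: LabelRaster | None = None
    tract_census: CensusTable | None = None
    subdivision_census: CensusTable | None = None
    water_mask: np.ndarray | None = None
    protected_mask: np.ndarray | None = None
    inhabit_config: wt.InhabitabilityConfig = field(default_factory=wt.InhabitabilityConfig)
    travel_schedule: wt.TravelRangeSchedule = field(default_factory=wt.TravelRangeSchedule)

    # derived (or injected) stage products
    scaling_fits: dict[int, sc.ScalingFit] | None = None
    topo_fits: list[wt.RegionTopoFit] | None = None
    extent_series: list[ext.UrbanExtentSeries] | None = None

    _w0: ValueRaster | None = field(default=None, repr=False)
    _w1: ValueRaster | None = field(default=None, repr=False)
    _w2_cache: dict[int, ValueRaster] = field(default_factory=dict, repr=False)
    _division_of_county: dict[int, int] = field(default_factory=dict, repr=False)

    # -- unit bookkeeping ---------------------------------------------------

    def division_of_county(self, county_id: int) -> int:
        if county_id not in self._division_of_county:
            sel = self.county_labels.labels == county_id
            if not sel.any():
                raise KeyError(f"county {county_id} absent from label raster")
            self._division_of_county[county_id] = int(self.division_labels.labels[sel][0])
        return self._division_of_county[county_id]

    def county_ids(self) -> np.ndarray:
        return self.county_labels.ids()

    # -- stage products -----------------------------------------------------

    def ensure_scaling_fits(self) -> dict[int, sc.ScalingFit]:
        """Per-division power-law fits at the baseline decade.

        Census areal extents (continuous km²) are preferred over whole-pixel
        footprint areas when the registry carries them.
        """
        if self.scaling_fits is None:
            cell = self.spec.cell_area_km2
            fits: dict[int, sc.ScalingFit] = {}
            for div in self.division_labels.ids():
                areas, pops = [], []
                for ua in self.registry.in_division(int(div)):
                    if ua.footprint is None or not ua.exists_in(self.baseline_decade):
                        continue
                    areas.append(ua.area_km2 if ua.area_km2 is not None
                                 else len(ua.footprint) * cell)
                    pops.append(ua.population(self.baseline_decade))
                if areas:
                    fits[int(div)] = sc.fit_area_population_scaling(areas, pops, int(div))
            self.scaling_fits = fits
        return self.scaling_fits

    def ensure_topo_fits(self) -> list[wt.RegionTopoFit]:
        """Per-region density–elevation fits at the baseline decade.

        County density uses inhabitable area only (w0 > 0 pixels).
        """
        if self.topo_fits is None:
            w0 = self.ensure_w0().values
            cell = self.spec.cell_area_km2
            mean_z = zonal_mean(self.elevation, self.county_labels)
            pops = self.county_census.populations(self.baseline_decade)
            fits = []
            for reg in self.region_labels.ids():
                dens, zs = [], []
                for cid in self.county_ids():
                    cid = int(cid)
                    sel = self.county_labels.labels == cid
                    if int(self.region_labels.labels[sel][0]) != int(reg):
                        continue
                    inhab = float((w0[sel] > 0).sum()) * cell
                    p = pops.get(cid, 0.0)
                    if inhab > 0 and p > 0:
                        dens.append(p / inhab)
                        zs.append(mean_z[cid])
                if len(dens) >= 3:
                    fits.append(wt.fit_topo_relation(dens, zs, region_id=int(reg)))
            self.topo_fits = fits
        return self.topo_fits

    def ensure_extents(self) -> list[ext.UrbanExtentSeries]:
        """Backproject every urban area's extent series from its baseline footprint.

        The baseline decade keeps the observed footprint itself; other
        decades get the scaling-law prediction (clamped to the footprint
        for forward decades without observed extents).
        """
        if self.extent_series is None:
            fits = self.ensure_scaling_fits()
            cell = self.spec.cell_area_km2
            series = []
            for ua in self.registry:
                if ua.footprint is None:
                    raise ConfigError(f"urban area {ua.urban_id} has no baseline footprint")
                fit = fits[ua.division_id]
                targets = {
                    t: (len(ua.footprint) * cell if t == self.baseline_decade
                        else sc.predict_area(ua.population(t), fit))
                    for t in self.decades
                    if ua.exists_in(t)
                }
                if not targets:
                    continue
                series.append(
                    ext.delineate_history(
                        ua.footprint, targets, cell, center=ua.center, urban_id=ua.urban_id
                    )
                )
            self.extent_series = series
        return self.extent_series

    def extent_raster(self, decade: int) -> LabelRaster:
        return ext.extent_label_raster(self.ensure_extents(), decade, self.spec)

    # -- weight rasters -----------------------------------------------------

    def ensure_w0(self) -> ValueRaster:
        if self._w0 is None:
            tract_pops = None
            if self.tract_census is not None:
                tract_pops = self.tract_census.populations(self.baseline_decade)
            self._w0 = wt.inhabitability_mask(
                self.elevation,
                water_mask=self.water_mask,
                protected_mask=self.protected_mask,
                tract_labels=self.tract_labels,
                tract_populations=tract_pops,
                division_labels=self.division_labels,
                config=self.inhabit_config,
            )
        return self._w0

    def ensure_w1(self) -> ValueRaster:
        if self._w1 is None:
            self._w1 = wt.topo_weight(
                self.elevation, self.ensure_topo_fits(), self.region_labels
            )
        return self._w1

    def w2_for(self, decade: int) -> ValueRaster:
        """Socioeconomic-desirability raster for one decade.

        Urban pixels: r**(-lambda) from their own center; rural pixels:
        gravity market potential over urban areas within D_t.
        """
        if decade not in self._w2_cache:
            fits = self.ensure_scaling_fits()
            series = {s.urban_id: s for s in self.ensure_extents()}
            w2 = np.ones(self.spec.shape)
            urban_mask = np.zeros(self.spec.shape, dtype=bool)
            centers, pops = [], []
            for ua in self.registry.existing_in(decade):
                s = series.get(ua.urban_id)
                if s is None or not s.exists_in(decade):
                    continue
                px = s.extent_pixels(decade)
                lam = fits[ua.division_id].lambda_
                w2[px[:, 0], px[:, 1]] = wt.urban_distance_weight(
                    px, s.center, lam, self.spec.cell_size_km
                )
                urban_mask[px[:, 0], px[:, 1]] = True
                centers.append(s.center)
                pops.append(ua.population(decade))
            rural = (self.county_labels.labels > 0) & ~urban_mask
            rpx = np.argwhere(rural)
            d_t = self.travel_schedule.range_km(decade)
            w2[rural] = wt.market_potential(
                rpx, np.array(centers).reshape(-1, 2), np.array(pops),
                d_t, self.spec.cell_size_km,
            )
            self._w2_cache[decade] = ValueRaster(self.spec, w2)
        return self._w2_cache[decade]
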