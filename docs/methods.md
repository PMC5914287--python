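# Methods

This note documents the modelling choices behind `dasypop`: the allocation
framework, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Spatial model

Everything lives on one planar, equal-area, row-major, north-up grid of
square pixels (default 1 km). Distances are Euclidean between pixel
centers in projected km; areas are pixel counts × cell area, with no
sub-pixel polygon intersection — the framework's products are whole-pixel
grids, so finer geometry would be spurious precision. Real inputs must be
pre-projected to such a grid; the package does no reprojection. Labels are
1-based positive integers with 0 reserved for "outside the universe";
value rasters use NaN off-universe. Raster I/O supports the Esri ASCII
grid (plain text) and TIFF; census tables are long-format CSV
(`unit_id, decade, population[, area_km2]`).

## Allocation (models M1–M5)

Within each allocation zone — an (urban area ∩ county) or a county's rural
remainder — pixel populations are the zone count times normalized
per-pixel weights `w0·w1^s·w2^d`. Consequences of this form:

- **Conservation is exact** (up to float rounding ~1e-15 relative): zone
  and hence county and national totals always match the census input.
  Fractional persons are retained; rounding to integers would break this.
- **Zone-constant rescaling cancels.** Max-normalizing each weight layer
  to 1 within a division (the convention for published weight grids) is
  cosmetic; a property test asserts it.
- **Degenerate zones fall back to uniform.** A zone whose pixels are all
  non-inhabitable still receives its population (uniformly, with a logged
  warning and a diagnostics flag) rather than dropping people;
  conservation is treated as inviolable.
- Urban zones are intersected with counties so county bookkeeping stays
  exact even for multi-county agglomerations (the synthetic generator
  avoids that case; the registry supports per-county shares).

M1 uses one county-wide zone and uniform weights; M2 splits urban/rural;
M3 multiplies in w0; M4 adds `w1^s`; M5 adds `w2^d`. With `s = 0`, M4
reduces to M3 pixel-for-pixel, and with `d = 0`, M5 reduces to M4 — tested
as exact identities.

## Urban scaling and extent backprojection

`A_U = α_δ P_U^{β_δ}` is fitted per division by OLS of log10 area on log10
population at the baseline decade (the newest decade with full footprint
coverage). The regression direction follows the prediction direction —
area is predicted from population — rather than an orthogonal fit. Any log
base gives the same exponent. When the registry carries census areal
extents (continuous km² values) those are preferred over whole-pixel
footprint counts, which would inject quantization noise into the fit.
Scaling parameters are held constant over decades; there is no data to
constrain their drift, and the density gradient `λ_δ = 2 − 2β_δ` inherits
the same stationarity.

Backprojection sorts the baseline footprint by (distance to center, angle
from east, row, column) — a total order, so extents are reproducible
across platforms — and takes the prefix of `round(A_U,t / cell)` pixels,
clamped to [1, footprint size]. The center is the footprint pixel nearest
the unweighted centroid (ties to smallest row, then column); whether the
original study used centroids or designated city centers is not
determinable, and the choice is recorded in output metadata. The baseline
decade keeps its observed footprint; forward decades without observed
footprints use the clamped prediction (backprojection should shrink, never
grow). Extents are nested across decades by construction, matching the
monotone-urbanization assumption. Corridor or riverine growth patterns are
deliberately out of scope.

## Influence coefficients

**w0 (inhabitability, static).** Excludes protected pixels, 4-connected
water patches of at least 1 km², elevation above 3500 m, and pixels in
census tracts whose population at the calibration decade falls below a
per-division cutoff (candidates 1000–3000; areal weighting systematically
overfills low-population tracts, and masking them lowers overall error).
Tract boundaries are modern, so the cutoff is applied as a static mask
from the calibration-decade tract table only.

**w1 (topography, static).** `exp(m_μ z_k)` from per-region OLS of ln
county density (over inhabitable area only) on county mean elevation.
A significance gate (`p < 0.05`) decides whether a region is weighted at
all — regions with no significant relation pass w1 = 1 through, the
treatment the original analysis gave Colorado. Optional elevation bands
support sub-region fits where one coastal city disrupts an otherwise
monotone relation.

**w2 (desirability, per decade).** Urban pixels: `max(r, r_min)^{−λ_δ}`
from their own center. Rural pixels: gravity market potential, the
inverse-square-weighted mean population of urban areas within the travel
range `D_t` — algebraically bounded by the smallest and largest in-range
urban population, and equal to `P_U` exactly when a single source is in
range (computed as such, bypassing the quotient). Two numerical choices:

- `r_min` = half a cell prevents the `r → 0` singularity at the
  center-containing pixel.
- Rural pixels with *no* urban area in range get the neutral weight 1
  rather than 0: excluding them would zero out remote counties' population
  and violate conservation. Allocation there degrades to `w0·w1^s`.

`D_t` anchors default to 30 km at the earliest decade and 100 km at the
baseline, interpolated log-linearly in time ("exponentially increasing"
travel range) and clamped beyond the anchors. The 30-km figure is the
physically plausible daily travel range for a pre-industrial decade; the
anchors are configurable.

## Calibration and validation

MARE (mean absolute relative error over reference units of area ≥ 1 km²)
is the objective; tract-level MARE is primary, county-subdivision MARE a
coarser cross-check. Units with zero observed population are excluded —
the relative error is undefined there — and the unit count is always
reported alongside. Calibration is sequential per division, mirroring the
nested model construction: `s` by grid search under M4 (d absent), then
`d` under M5 with `s` fixed; ties go to the smaller value, preferring the
weaker weighting. A joint 2-D search is available behind a flag since a
sequential search can in principle miss interactions. Two `d`-grid presets
ship: the default extends down to 0.02 because desirability weights span
orders of magnitude and the objective is most sensitive at the low end;
a coarse 0.2–3.0 preset matches the `s` grid. Model effectiveness is the
MARE reduction of each model over its next-simpler neighbor; the deltas
telescope to MARE(M1) − MARE(M5).

## Synthetic worlds: what they emulate, and what not

The generator builds study regions satisfying the framework's assumptions
*exactly*, so downstream error is attributable to the algorithms:

- counties are rectangular blocks tiling vertical division strips (one
  region per division by default); tracts and subdivisions partition
  counties;
- county mean elevations are stratified over the elevation range within
  each division (every division keeps populous low-elevation counties, so
  per-division scaling fits are always identifiable), with ~25 m of pixel
  texture;
- ln county density = m·z + b + noise holds by construction; county
  population is density × inhabitable area;
- each sufficiently populous county holds one disc-shaped urban area,
  grown concentrically from the county center, with continuous census
  area `α P^β · 10^ε` and footprint `round(area/cell)` pixels;
- populations follow exponential per-decade trajectories with mild
  county-level rate jitter; urban areas leave the registry in decades
  where they fall below the 2500-person census threshold (their pixels
  revert to rural);
- per-pixel ground truth is drawn from the full M5 generative form with
  the true parameters, so M5 with true inputs reproduces truth bit-exactly
  and parameter recovery is well-posed;
- optional "sparse tracts" scale the truth's suitability down inside a
  subset of non-urban tracts, producing the low-population-tract
  overestimation that motivates the w0 cutoff.

Default study conditions: β = 0.95 with log10-scatter 0.05 and
α = 0.002 km²·persons^−β (a 10⁴-person town occupies ≈ 12 km²);
m = −0.0015 /m (density falls e-fold per ~670 m of elevation) with ln-noise
0.3 and sea-level density e^5.0 ≈ 150 /km²; urban fraction 0.4; growth
1.3× per decade; 5% water and 5% protected area; s = 1.0, d = 0.6;
decades 1790–2010 on a 90×90 km grid with 3 divisions × 9 counties. These
sizes keep full parameter-recovery experiments (10 seeds × 29 grid-search
allocations each) in seconds on one CPU while leaving ≥3 urban areas per
division and ~100 validation tracts.

What synthetic worlds do **not** emulate: real geography (coastlines,
corridors, multi-county agglomerations), migration, boundary changes over
time, census undercount, or deviations from the model's own assumptions
(non-concentric growth, time-varying β, expanding inhabitable area).
Passing recovery tests therefore demonstrates the *internal* correctness
and identifiability of the framework — that the pipeline recovers the
parameters of a world that satisfies its assumptions — not the accuracy
of those assumptions for any real region.

## Known limitations

- Concentric, monotone urban growth is a strong simplification; real
  extent error is dominated by it, not by the algorithmic steps verified
  here.
- The scaling law and inhabitability mask are static over 22 decades.
- Tract cutoffs use modern tract geometries applied backwards in time.
- No uncertainty quantification; outputs are point allocations.
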