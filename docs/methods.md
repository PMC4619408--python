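# Methods

`finedgvm` projects vegetation at fine (sub-kilometre) spatial resolution in
topographically complex terrain.  The pipeline has five scientific stages —
grid/soil construction, climate downscaling, a reduced vegetation model, a
biome decision tree, and map-agreement evaluation — plus a synthetic-data
generator that supplies every input with known statistical structure so the
whole chain is testable without external archives.

## Grid, areas, and elevation

The study grid is a regular geographic raster of cell-centre points
(longitudes signed decimal degrees, west negative; rows stored
south-to-north).  Elevation is attached by a *containing-cell* lookup into a
coarser DEM: each fine point receives the value of the single DEM cell whose
half-open extent `[west, east) × [south, north)` contains it — deliberately
not an interpolation, so fine points inherit sharp DEM structure and edge
points are assigned deterministically.  Box areas use the exact spherical
zone formula `R² Δλ (sin φ₂ − sin φ₁)` on the authalic sphere
(R = 6371.0072 km); the formula is exact on the sphere, so the only
approximation relative to an ellipsoidal calculation is the Earth model
itself (≲ 0.1 %).

## Soil hydraulics and roots

The soil column is the top metre in eight layers (50, 50, 100, 100, 100,
200, 200, 200 mm).  Volumetric water contents at −1500 kPa (wilting point),
−33 kPa (field capacity) and saturation come from the Saxton et al. (1986)
sand/clay regression for the retention curve ψ = A·θ^B and porosity;
per-layer millimetres of water are fraction × thickness, and plant-available
water capacity (AWC) is field capacity minus wilting point.  Textures
outside the regression's stated validity window (sand 5–95 %, clay 5–60 %)
are clamped with a warning rather than extrapolated.  Root fractions follow
the Jackson et al. (1996) exponential profile Y(d) = 1 − β^d (d in cm) with
a single configurable β (default 0.966, a published temperate-vegetation
value), truncated at 1 m and renormalised to sum to 1.

## Climate downscaling

Downscaling is the anomaly (delta-change) method with an elevational
correction:

1. **Local lapse rates.**  For each coarse cell and calendar month, the
   slope of a weighted least-squares regression of the climate variable on
   elevation over a moving window (default 11×11 coarse cells), with
   tricube weights on great-circle distance from the window centre.
   Windows with fewer than `min_points` (10) valid cells, or with a
   weighted elevation spread under 10 m, are masked — a per-metre slope is
   not identifiable without elevational contrast, and regressing noise on a
   near-constant regressor yields unbounded estimates.  The 11×11 default
   was calibrated once on the package's own synthetic world so the
   estimator's mean absolute slope error stays within 5 % at a noise
   standard deviation of 0.5 °C with spatially correlated noise; a 9×9
   window leaves the estimator just outside that tolerance.
2. **Base-climatology interpolation.**  Each fine point combines the four
   surrounding coarse nodes with inverse-great-circle-distance weights,
   every node value first adjusted by `lapse × (z_fine − z_node)`.  Fine
   points coincident with a coarse node take that node's value verbatim
   (the adjustment vanishes when elevations agree).  The elevational
   adjustment is additive for all variables, with physical clamps applied
   afterwards (sunshine to [0, 100] %, precipitation floored at 0 mm).
3. **Anomalies.**  Temperature anomalies are differences from the
   base-period monthly mean; precipitation, sunshine and cloud anomalies
   are ratios.  A zero base-period mean defines the ratio anomaly as 1 ("no
   change") and is counted in the log — this avoids division by zero in
   dry-month deserts.  Anomalies are interpolated to the fine grid with the
   same distance-weighted bilinear stencil but *without* elevational
   adjustment (only base climatologies carry the lapse correction), then
   added to / multiplied onto the fine base climatology.  Cloud is
   converted to possible sunshine as `100 − cloud`.
4. **Spin-up.**  The spin-up series tiles the first 30 input years after
   removing the long-term trend: per cell and calendar month, a loess
   (locally weighted, degree-1) regression across the 30 annual values
   (span 0.5) is subtracted with the mean preserved, and the detrended
   block is repeated to the configured spin-up length (default 800 years =
   9600 months).

## Reduced vegetation model

Ten plant functional types (PFTs) are screened against bioclimatic limits:
minimum/maximum coldest-month mean temperature (Tc), minimum growing degree
days above 5 °C (GDD5), and minimum annual temperature range (Tw − Tc).
The limit table ships as a versioned CSV (`data/pft_params.csv`); two of
the ten PFTs are herbaceous, and the herbaceous limits leave them almost
unconstrained — cold cells are kept near-barren by the productivity term
instead.  GDD5 uses the standard DGVM pseudo-daily convention: daily
temperatures linearly interpolated between monthly means anchored at month
midpoints on a 365-day year, summed over `max(0, T − 5)`, averaged over a
30-year window; Tc and Tw are the window-mean coldest and warmest calendar
months.  The same 30-year window is applied to all four limits.

Survivors then share cover through an explicit equilibrium stand-in for a
process DGVM (the classifier consumes only the `CellSummary` interface, so
a full process model can replace this module without touching anything
downstream):

* **Moisture.**  A single-bucket water balance driven by the mean annual
  cycle: capacity = column AWC, monthly inflow = precipitation, outflow =
  `min(PET, store + P)` with Thornthwaite PET (no day-length correction),
  iterated to a periodic steady state.  The moisture index is the annual
  ratio α = ΣAET/ΣPET (1 when PET is zero all year) — the
  evaporative-demand-weighted index used throughout the biome-model
  lineage.  A monthly-mean of AET/PET was considered and rejected: in
  winter-wet climates every low-demand month contributes a ratio near 1,
  which hides summer drought and makes semi-arid interiors look mesic.
* **Productivity score** s = f(GDD5) · α · g(CO₂) with
  f(G) = G/(G + 500) (half-saturation 500 degree-days) and
  g(c) = 1 + 0.2·ln(c/368), increasing and equal to 1 at the 368 ppm
  historical reference.  Total woody cover is 0.95·s when any woody PFT
  survives; it is split among surviving woody PFTs in proportion to a
  Gaussian affinity for the cell's Tc (class centres −15/5/22 °C for
  boreal/temperate/tropical, sd 10 °C).  Equal-width Gaussians make the
  boreal:temperate weight ratio strictly monotone in Tc, so warming can
  never flip a temperate-dominant cell back to boreal-dominant.
  Herbaceous PFTs fill a fraction 0.8·s of the remaining space.
* **Height** per woody PFT is s times a thermal-class cap (boreal 18 m,
  temperate 30 m, tropical 35 m).
* **Fire return interval** FRI = 15 yr / (fuel × dryness), fuel = total
  FPC, dryness = 1 − α, clipped to [1, 10⁴] yr.  The 15-yr scale is a
  stand-in calibration chosen so that fire-prone low-cover cells
  (fuel × dryness ≈ 0.25–0.31, the reachable maximum of the product in
  this model) fall below the 63-yr classification split while mesic
  forests (< 0.17) stay above it; no process content is claimed for it.

CO₂ enters as a single per-run value (368 ppm historical, 734 ppm for the
default future scenarios); a piecewise-linear schedule helper exists for
transient drivers, but an equilibrium model has no use for year-by-year
values.  Likewise the 800-year detrended spin-up block is constructed and
validated during a run, but cannot alter an equilibrium summary — it
matters only when a stateful process model is plugged in.

## Biome classification

A fixed decision tree over the cell summary, evaluated in this order:

1. GDD5 ≤ 350 degree-days → **alpine grass/shrub** (precedes every other
   rule);
2. total FPC < 0.10 → **barren**;
3. woody FPC ≤ 0.30: FRI < 63 yr → **savanna/grassland/steppe**; otherwise
   moisture < 0.15 → **xeric shrub**, else **shrub-steppe**;
4. woody FPC > 0.30: maximum woody height > 10 m → forest, ≤ 10 m → open
   forest/woodland;
5. thermal modifier from the dominant woody PFT (argmax FPC, ties broken
   by table order): boreal-dominant → **cold**, otherwise **cool**;
   cool forest with Tc ≥ −2 °C and annual precipitation ≥ 1200 mm →
   **maritime cool forest**; cool open forest/woodland with temperate
   broadleaf evergreen FPC ≥ 0.05 → the **broadleaf-evergreen** variant.

The 350 / 0.30 / 63 / 10 thresholds are published decision boundaries and
are pinned by boundary tests (350 alpine vs 351 not, 0.30 eligible vs 0.31
not, FRI 62 vs 63, height 10.0 vs 10.000001).  The barren (0.10), moisture
split (0.15), maritime (−2 °C, 1200 mm) and broadleaf-evergreen (0.05)
constants are reconstructions of branches the source scheme leaves
implicit; all live in `RuleConfig` and none is presented as an observed
value.  "Woody" and "tree" FPC are treated as synonymous (the woody PFTs
are trees), and herbaceous cover does not count toward the 0.30 threshold.
The classifier is total and deterministic; its codomain on unmasked cells
is exactly the 11 categories.

## Evaluation

Simulated biome maps and observed class rasters are collapsed to
forest/grass/shrub through explicit mapping tables.  The default biome
mapping sends all forest and open forest/woodland classes to forest,
savanna/grassland/steppe to grass, shrub-steppe and xeric shrub to shrub,
and excludes alpine and barren; it is a configurable default, not an
authoritative crosswalk.  Classes a vegetation model does not simulate
(agriculture, urban, wetland) are excluded.  Agreement is a 3×3 confusion
matrix over cells where both sides carry a compared class, with row
percentages (rendered to integer precision for presentation; full precision
kept internally) and an overall percent-correct that equals the
count-weighted mean of the diagonal.

## Synthetic world

The default scenario (`cascadia-toy`: 20×20 coarse cells at 0.25°, 240×240
fine at 1/48°, seed 42) states a maritime-mountain world:

* **Terrain** — a Gaussian meridional ridge (85 % of the 2500 m relief)
  plus spectrally synthesised fractal roughness (spectral slope β = 1.8,
  30 % of relief), floored at sea level; the coarse DEM is the exact block
  mean of the fine cells.
* **Temperature** — a sea-level seasonal cycle (mean 11 °C, amplitude
  9 °C, July peak) plus a prescribed lapse of −6.5 °C/km each month plus
  spatially correlated Gaussian noise (sd 0.5 °C, correlation length 2
  coarse cells).
* **Precipitation** — a winter-wet cycle (mean 90 mm/month, amplitude
  70 mm) enhanced linearly with elevation (doubling at 2000 m) and reduced
  east of the crest by a rain-shadow factor 1/(1 + 6·x), x the normalised
  distance beyond the ridge.  The shadow is part of the stated orographic
  structure: without it the whole domain is mesic and the dry-interior
  biomes never occur, which would silently stop exercising the savanna,
  shrub-steppe, xeric and barren branches end-to-end.
* **Anomalies** — temperature differences with a linear drift
  (0.01 °C/yr) plus AR(1) noise (φ = 0.3), recentred to exactly zero mean
  over the base period; ratio variables are log-normal with the log
  recentred, hence geometric mean 1 over the base period.
* **Soils** — spatially autocorrelated sand and clay fields (means 45/20 %,
  sd 15/8 %, correlation length 6 cells), texture uniform with depth.
* **Observed vegetation** — the classified truth map collapsed to
  forest/grass/shrub, each cell's label flipped to one of the other two
  classes with probability ε (so overall agreement ≈ 100(1 − ε) % with an
  exact binomial error model), plus planted agriculture and urban patches
  to exercise exclusions.

All generators are pure functions of (seed, parameters): child streams are
spawned with named keys and fields are drawn as whole arrays, so outputs
are independent of traversal order and bit-reproducible.

What a green synthetic test does **not** establish: the generator has no
weather-generator realism (no daily variability, no extreme events), its
noise is Gaussian and stationary, terrain is a single idealised ridge, and
soils ignore real pedogenic structure.  Green tests certify the pipeline's
operations and their couplings — not agreement with any observed landscape.

## Numerical choices and degenerate inputs

* Interpolation masks fine points outside the coarse node hull (a border
  band of half a coarse cell) rather than extrapolating.
* A coincident node (distance < 1 µm) takes the node value exactly instead
  of a 1/d weight.
* Ratio anomalies against a zero base are 1, flagged in the log.
* The water-balance bucket iterates at most 100 annual cycles or to a
  1e-10 mm steady state; PET = 0 all year yields moisture 1 by definition.
* FRI with zero fuel or zero dryness is capped at 10⁴ yr rather than
  infinite.
* Classifier ties for the dominant woody PFT break by table order
  (argmax's first hit).
* All NetCDF I/O uses the classic (NetCDF-3) format via scipy, the only
  backend guaranteed in the target environment; GeoTIFF export is out of
  scope for the same reason.

## Known limitations

The vegetation stage is an equilibrium stand-in: no carbon pools,
demography, establishment/mortality, heat or cold stress events, process
fire behaviour, land use, or dispersal.  Percent-agreement is the only map
statistic (no kappa or fuzzy agreement).  Only geographic lat-lon grids are
supported — no projections, no DEM void-filling, no vertical datum
handling.  Real CRU/SRTM/CMIP3-scale archives are out of scope; external
data can be supplied through the NetCDF interfaces but the shipped
experiments run on the synthetic world.
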