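# Methods

## The model

The pipeline models habitat suitability for pine-barren/sandplain-type
ecosystems from two edaphic variables only: percent sand and soil depth.
The underlying assumptions are (a) the target ecosystems are restricted to
deep, excessively drained sandy soils; (b) a soil survey's nested
map-unit → component → horizon tables carry enough information to score
both variables everywhere; and (c) a one-sided threshold — "at least as
sandy and deep as typical known locations" — separates candidate habitat
from the rest of the landscape. Climate, hydrology and disturbance regime
are deliberately out of scope: the model finds *potential* habitat, not
current open-canopy cover.

### Aggregation

- **Soil type (component).** Percent sand is the thickness-weighted mean
  over all horizons of the profile. Horizons with no sand measurement are
  dropped from numerator *and* denominator (weight renormalization), never
  imputed as 0 — zero is a legal sand value. A profile with no sand data at
  all carries a null, which propagates to "nodata" in the map rather than
  "unsuitable". Soil depth is the depth to the nearest restrictive layer,
  capped at `cap_depth` = 200 cm; a profile with no reported restrictive
  layer gets the cap. The cap applies only to restrictive depth: horizon
  weighting always covers the entire described profile, because the profile
  mean is defined over the whole profile and truncating it at the cap would
  silently change the statistic for very deep profiles.
- **Map unit / location.** Both are area-weighted means over soil types.
  Within a map unit the survey has no sub-polygon geometry, so a component's
  area inside any polygon is the polygon-intersection area times the
  component's areal fraction — the only within-unit area information a
  SSURGO-style survey carries. Intersection slivers under 1 m² are dropped
  as overlay noise.

### Calibration

Training locations are a uniform random subset (fraction 0.7 by default,
round-half-up on `fraction × N`, so 156 locations give 109/47). Statewide
statistics weight each training location by its total area; the weighted SD
uses the population form `sqrt(Σw(x−m)²/Σw)` — the simplest well-defined
estimator, equal to the ordinary population SD with each value replicated
in proportion to its weight, and invariant to rescaling all weights.
Each threshold is `mean − 1·SD`, computed from the unrounded mean and SD
and then rounded half-up to an integer by default (the thresholds are used
as integers; full-precision values are retained in the result). Comparisons
are inclusive (≥): "at least" as sandy and deep.

Locations whose entire composition lacks sand data are excluded from
calibration (their mean is undefined) and counted in the run log.

### Classification, exclusion, summaries

Map units are classified from their fraction-weighted values, mirroring the
location convention, rather than by dominant component — a documented
assumption, since the survey does not say where inside a unit each
component lies. The raster map of record uses codes 1 suitable /
0 unsuitable / 2 excluded / 255 nodata; cells under the wetland/open-water
exclusion mask become excluded regardless of soil state, and the mask is
nearest-neighbour resampled onto the soil grid when resolutions differ
(e.g. a 30 m land-cover mask onto a 10 m soil grid). Land-cover summaries
reclassify NLCD-style codes into forest / open / agriculture / urban (plus
"other"; water and wetlands are the excluded class) and report per-category
suitable areas and proportions; when region polygons tile the extent, each
cell counts in exactly one region (the first region containing its centre),
so per-region summaries add up exactly to the global one.

### Validation

Three overlap statistics, all against the raster map of record so excluded
cells count as non-suitable:

1. **Held-out locations** — per-polygon suitable-area fraction. Because
   "fell within the map" is ambiguous for a polygon (any overlap? majority?
   centroid?), the report emits both the continuous per-location fractions
   and a binarized summary (fraction of locations whose overlap exceeds a
   configurable cutoff, default 0.5) rather than committing to one reading.
2. **Non-focal ecosystems** — area-weighted overlap aggregated per type; a
   good map scores low here.
3. **Species occurrences** — per-species fraction of points on suitable
   cells, with means over all species and over the high-affinity subset.
   Points with estimated (place-name) coordinates are ordinary points; the
   provenance is a label, not a weight. Cell membership is half-open, so a
   boundary point belongs to exactly one cell; points off the map extent
   count as non-overlapping and are logged.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
any actual geography. A rectangular extent is tessellated into square map
units; contiguous rectangular blocks of units form "sandy patches"
(`patch_fraction` ≈ 0.3 of units). Patch components draw sand from
Normal(87, 11) truncated to [0, 100] and restrictive depth from
Normal(193, 33) — the regime of the published training statistics — with
draws at or beyond the 200 cm cap recorded as "no restrictive layer
reported". Background components are loamier and shallower
(sand ~ Normal(45, 15), depth ~ Normal(90, 40)). Components per unit
(1–3, Dirichlet fractions), horizons per component (2–5) and location sizes
(log-uniform 1–25 ha) are arbitrary-but-realistic choices, fixed once.

Two constructions keep ground truth exact rather than estimated:

- **Mean-preserving horizon jitter.** Horizon sands vary around the
  component draw with a zero thickness-weighted-mean perturbation, rescaled
  to stay inside [0, 100]; the profile's depth-weighted mean therefore
  equals the component draw exactly, and the truth table matches the
  pipeline's aggregation to float precision.
- **Exact land-cover allocation.** Per-category cell counts are fixed by
  largest-remainder apportionment of the configured fractions over the
  patch and background cell populations (placement and code choice are
  seeded draws), so category bookkeeping is exact to one cell.

Locations are squares placed fully inside a single map unit, chosen among
patch units with probability `location_patch_bias` (default 1.0: known
high-quality remnants sit on the soils that support them; lowering it
creates mislabelled training data). Species points land on a uniformly
chosen truly suitable, non-excluded cell with their affinity probability
(0.9 high / 0.6 other by default) and uniformly in the extent otherwise.
All randomness comes from integer-seeded generators keyed by
`(seed, stage)`, so every artifact is byte-reproducible per seed and each
stage is reproducible in isolation.

What the generator does **not** emulate: spatial autocorrelation beyond the
patch blocks, shared soil types across map units, non-square geometries,
CRS reprojection, and any correlation between land cover and soil beyond
the patch/background split. Passing tests therefore demonstrate the
correctness of the aggregation, calibration, overlay and validation
machinery — not the ecological adequacy of the two-variable model on real
landscapes.

### Recovery targets

Truncation and censoring shift the realized distributions away from their
nominal parameters: the analytic mean/SD of sand truncated to [0, 100] is
84.5 ± 9.1 (not 87 ± 11), and of depth censored at 200 cm is 183.0 ± 21.6
(not 193 ± 33). Parameter-recovery checks therefore compare calibrated
statistics against these closed-form values (`scipy.stats.truncnorm`; the
censored-normal moments in closed form), and the manifest's "true
thresholds" are round-half-up of analytic mean − SD (75% sand, 161 cm
depth for the defaults). The end-to-end area check classifies the survey
at those true thresholds and compares against the generator's bookkept
count of suitable non-(water/wetland) cells; per-seed *calibrated*
thresholds fluctuate with the training draw, and that sampling variation
is assessed by the recovery check, not the overlay check.

## Numerical and design choices

- `cap_depth` = 200 cm, the maximum depth soil surveys describe; the
  published depth statistics (193 ± 33 cm, 160 cm threshold) are only
  internally consistent with a centimetre cap.
- Round-half-up for split sizes and integer thresholds (0.7 × 156 = 109.2
  → 109; 87 − 11 → 76).
- Rasterization assigns a cell to the polygon intersecting its centre;
  centres are never on edges, so tessellations aligned with the grid get
  exact areas, and the vector/raster area paths agree within 1% on convex
  non-aligned scenes at 10 m cells. Cell ownership for points is half-open
  (a point on a shared edge belongs to the cell right/below it).
- Default problem sizes: the shipped scenario is 20 km × 20 km with 1 km²
  map units and 50 m cells, and the recovery sweep uses 20 seeds × 200
  locations — large enough for stable statistics while keeping a full test
  run in well under a minute per sweep.
- Geometry areas are planar, in the layer's (assumed metre) CRS; no
  geodesic computation and no reprojection — inputs must share a projected
  CRS, and a missing CRS is a warning plus the planar-metre assumption.
- Vector I/O is GeoJSON; raster I/O is single-band TIFF with
  ModelPixelScale/ModelTiepoint/GDAL-nodata tags written directly, the CRS
  string carried in the image description. CSV floats are written with
  `repr` and parsed with round-trip precision so reports and tables
  round-trip exactly.

## Known limitations

- Overlapping ecosystem locations are treated independently; shared area is
  counted in each.
- The exclusion mask is generic (any nonzero raster); whether wetland/water
  omission should come from the land-cover product or from survey hydric
  flags is the caller's choice.
- No texture-class inference: percent sand must be numeric. Surveys that
  report only texture names need preprocessing.
- One split, one seed: no repeated-split uncertainty quantification is
  built in, though a seed loop over `calibrate` provides it trivially.
- Point locations for *ecosystem* polygons are rejected rather than
  buffered; buffering policy is left to the user.
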