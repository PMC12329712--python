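# Methods

This note documents the models, the synthetic study system, the numerical
choices and the known limitations of `lusa`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Scenario data model

Land use is represented as per-cell category fractions on a single
rectangular grid in a Cartesian equal-area pseudo-CRS (default 50 × 50
cells of 10,000 ha, i.e. 10 × 10 km).  Raw scenario grids carry seven
categories (forest, grassland, pasture, cropland, forest plantation,
mosaic, other); before indicator computation, cropland is split into
annual / perennial / semi-perennial by share tables (per admin unit, with
a global fallback) and the mosaic class is folded into its component uses.
The split procedures behind real disaggregated products are not public in
detail, so shares are user data; the defaults (70/10/20 cropland,
40/30/20/10 pasture/annual/grassland/forest mosaic) are plausible
Brazilian compositions, not calibrated values.

Disaggregation is mass-conserving per cell *bitwise*, not merely within a
tolerance: the residual subtype takes `raw − (sum of the other parts)` in
the same left-to-right association used to verify the balance, followed by
a one-ulp `nextafter` walk (and, for round-to-even ties at the residual's
ulp spacing, a parity nudge of the largest earlier part).  Fraction-sum
validation uses ε = 10⁻⁶, reflecting float accumulation across eight
categories.

## Synthetic scenario generator

The generator emulates the study conditions the pipeline is designed for;
its defaults are fixed and are not tuning knobs.

* **National trajectories.**  Each scenario preset carries the relative
  2015–2050 change of every category total as published for Brazil's three
  SSP-RCP land-use projections (e.g. sustainability pathway: forest +23%,
  grassland −7%, pasture −36%, cropland −15%, plantation −54%, other
  +23%; middle-of-the-road: forest −1%, grassland −19%, pasture +12%,
  cropland +21%, plantation −7%, other +9%; inequality: forest −3%,
  grassland −29%, pasture +26%, cropland +26%, plantation +9%, other
  +10%).  Base-year national shares (forest 45%, grassland 20%, pasture
  19%, cropland 9.4%, plantation 1.1%, mosaic 2.5%, other 3%) approximate
  the Brazilian 2015 composition.
* **Area closure.**  Arbitrary published trajectories do not close the
  land balance exactly (the residual is ≈ +1.8% of territory under the
  sustainability preset).  One designated balance category — mosaic, the
  category without a published trajectory — absorbs the residual, so all
  stated endpoints are met exactly and total area is conserved exactly.
* **Allocation.**  Between timesteps, category totals follow linear paths
  and per-cell fractions are re-fitted by biproportional (RAS) scaling of
  a seed matrix equal to the current pattern plus a smoothed frontier term
  (Gaussian filter of each category layer), so expansion attaches to
  existing patches.  This stands in for a full land-use allocation model,
  which is outside the package's scope; it produces spatially contiguous,
  deterministic change but no road networks, protection zoning or
  suitability economics.  When a step's demand is unchanged the map is
  frozen (no gratuitous reallocation).
* **Landscape.**  Continuous layers are smoothed Gaussian fields with a
  latitudinal temperature/precipitation gradient; biomes and states are
  Voronoi partitions; climate zones and soil classes are quantile splits
  of smooth fields.  Climate and topography are constant over the horizon,
  so land use is the only driver of indicator change.
* **Species.**  Each synthetic species has a smooth-blob expert range mask
  (30–60% grid coverage) and a sparse logistic suitability: 2–4 active
  predictors with standardized weights of magnitude 0.8–2, intercept
  calibrated by bisection to a mean within-range suitability of 0.35.
  Active predictors are restricted to layers mutually correlated below
  0.5 *within the range mask* — stricter than the pipeline's 0.7 pruning —
  so the generating model remains identifiable after correlation pruning;
  without this, collinear land-use fractions (forest vs grassland-pasture
  within a range can correlate above 0.7) would make "recover the true
  predictors" ill-posed.  Presence records are rejection-sampled: uniform
  cells inside the mask accepted with probability equal to the true
  suitability; counts are Poisson with mean 66 per species, a typical
  per-species yield of cleaned occurrence-database extracts.
* **Reference tables.**  SOCref 40–80 t C/ha by soil and climate; F = 1
  for natural vegetation, 0.75–0.95 pasture, 0.5–0.8 croplands, 0.75–0.9
  plantations; forest biomass ≈ 55–150 t C/ha by biome (below-ground
  20–30% of above-ground), grassland biomass with root-dominated ratios;
  managed biomass in IPCC-default ranges.  2015 prices near Brazilian
  levels (soybean 290, coffee 2800, sugarcane 22, cattle carcass 2900
  USD/t) with ±10% state-level variation; price indices follow linear
  paths to scenario-specific 2050 multipliers (0.70 / 0.85 / 1.25);
  management factors and feed efficiency improve fastest under the
  sustainability preset.
* **Determinism.**  One master seed; every sub-generator uses a named
  substream (CRC32 of the stream name mixed into the seed), so adding a
  stage never perturbs another stage's draws, and the base-year map is
  identical across scenarios sharing a seed.

What passing tests on this system do *not* show: performance on real
occurrence data (taxonomic error, sampling bias beyond cell duplication),
real allocation patterns, real price volatility, or regrowth dynamics.

## Carbon accounting

Tier-1 stock accounting with instantaneous stock change on conversion:
natural vegetation is instantly mature, and soil carbon equilibrates
immediately — a documented simplification that ignores multi-decade
transition curves and overstates the speed (not the magnitude) of change.
Only the top 30 cm of soil is accounted; organic-soil drainage is ignored
(organic soils are a negligible share of the study system); dead wood and
litter are zero.  F applies to soil only, never biomass.  All unit
conversions (t C/ha → Gt, C → CO₂ at 44/12) are centralized.  A naive
per-cell/per-category loop implementation is kept as an in-package oracle;
vectorized stocks must match it to 10⁻⁹ relative.

## SDM pipeline

* Cleaning: invalid/out-of-bounds coordinates dropped, then one record per
  grid cell (first in input order).  No further bias correction.
* Pseudo-absences: uniform over cells outside the expert range, default
  1000, seeded.
* Class balance: per-point weights `w = N / (2 N_class)`, equalizing total
  presence and absence weight.
* Pruning at |Pearson r| ≥ 0.7 (common SDM practice; configurable).  Drop
  order: of the worst pair, the member with the larger mean |r| against
  the other retained predictors; ties drop the later column.  Constant
  predictors are dropped with a warning.
* Model selection: exhaustive AIC (2k − 2 ln L, k counting the intercept)
  over all non-empty subsets of the ≤ 10 pruned candidates — exact at
  ≤ 1023 weighted GLM fits, so no stepwise heuristics.  Ties resolve to
  the smaller subset, then lexicographic order.
* Thresholding: TSS evaluated at every distinct score plus 0 and 1,
  prediction `score ≥ t`; smallest maximizer returned.  The threshold is
  fitted on the full dataset after CV; CV supplies retention metrics only.
* Cross-validation: 5-fold, stratified by class, shuffled with an explicit
  seed; retention requires mean AUC > 0.5 and mean max-TSS > 0.
* Fitting delegates to a binomial GLM with variance weights
  (statsmodels); perfect separation is flagged, not fatal.  AUC is the
  rank/Mann-Whitney form with ties counted ½.

Identifiability note: presence-only records plus pseudo-absences drawn
outside the range form a case-control design whose logistic estimand
equals the generating slopes only when both classes share covariate
support; the intercept absorbs the sampling odds.  Coefficient-recovery
tests therefore use labelled within-range surveys (Bernoulli draws of the
true suitability), which identify all slopes; the pseudo-absence path is
tested against its own contracts (counts, exclusion, determinism,
retention of informative species).

## Revenue model

Revenue, not profit: production costs, irrigation, crop-mix heterogeneity
and forestry revenue are out of scope.  Prices are state-level with a
regional-average fallback (region membership is a config table; missing
region data raises).  Pasture yield assumes intensive systems in which
grass is part of a larger feed basket, embedded in the feed-efficiency
denominator.  All currency is base-year USD; exchange-rate handling is
upstream of the package.

## Trade-off analysis

National ratios are reported as |Δsecondary| per unit |Δprimary| with the
revenue axis in billion USD/yr, rounded to two significant figures for
presentation alongside full precision.  Improvement is "up" for all three
indicators.

Pixel classification uses a zero tolerance τ = 10⁻⁹ in native units
(exact-zero intent; configurable).  Two rules are the package's own
interpretations where the underlying approach is unspecified:

* the carbon and richness deltas collapse to one environmental axis by
  sign agreement, with disagreement resolved by the larger
  map-normalized |Δ| (ties to carbon);
* a neutral axis (|Δ| ≤ τ) joins the direction of the moving axis, which
  makes the seven categories mutually exclusive and exhaustive for every
  sign combination — verified by a fuzz test against a scalar reference
  rule.

Cells with revenue change but no land-use change are price-only outcomes.
The magnitude map is the geometric mean of the min-max-normalized absolute
deltas of the two indicators defining each cell's class (revenue alone for
price-only cells; 0 for no-change cells); a degenerate normalization range
yields 0 and is logged.

## Problem sizes and runtime

Defaults are desk-scale by design: unit tests use 20 × 20 grids, the
end-to-end acceptance run uses a 30 × 30 grid, three scenarios, six
species and 500 pseudo-absences (≈ 20 s), and the SDM recovery check uses
ten species at n = 5000 survey points each (≈ 1 min).  Full-country
headline magnitudes (hundred-Gt stocks, hundreds of species, 10⁵ cells)
require the real projections, occurrence databases and reference datasets,
which the package deliberately does not bundle; the synthetic system
verifies the machinery, not the geography.

## Known limitations

* No regrowth curves, dispersal constraints, or climate-driven projection.
* Logistic SDMs only — no ensembles (MaxEnt, BRT) and linear logits.
* RAS allocation has no economic or policy micro-structure.
* Raster I/O is plain-text ESRI ASCII with JSON sidecars; no reprojection
  between CRSs and no compressed/binary raster formats.
* Trade-off uncertainty (confidence bands on ratios) is not quantified.
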