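# Methods

## Potential-yield model

Potential yield is the step-wise light–temperature–water–soil revision
chain evaluated per raster cell over cultivated land:

* `YQ = (1e5/C)·F·Q·E` with `C` = 4.25 kcal g⁻¹, `F` = 0.03, `E` = 0.4 and
  `Q` the growing-season (May–October) **total** radiation in kcal cm⁻².
  Units: (kcal cm⁻²)/(kcal g⁻¹) = g cm⁻², and 1 g cm⁻² = 10⁵ kg ha⁻¹.
* `YT = (T/30)·YQ` with `T` the growing-season **mean** temperature. The
  ratio is clamped to [0, 1] by default: temperatures above the 30 °C
  reference or below zero would otherwise let a "correction" raise the
  potential or drive it negative, breaking the monotone-chain semantics.
  An unclamped mode is retained behind `StepModelParams.clamp_temperature_ratio`
  for sensitivity runs.
* `YW = f(w)·YT`, `YS = f(s)·YW` with both coefficients validated into
  [0, 1] (f(s) strictly positive). In humid monsoon regions rainfall
  exceeds evapotranspiration and f(w) = 1 is the standard choice; f(s) is an
  externally supplied soil-quality product — only the multiplication is in
  scope here, not its construction from pH/fertility/slope/texture.

One parameter set serves both paddy and dryland cells (rice dominates the
target cropping systems; `E` = 0.4 covers rice and corn); per-class
overrides are possible by running the chain twice with different params.
Yields are kept in kg ha⁻¹ internally and divided by 1000 only at county
aggregation, avoiding repeated rounding.

**Zonal aggregation** uses center-point assignment: a cell belongs to the
county polygon containing its center, the simplest deterministic rule.
County means are taken over cultivated cells (paddy ∪ dryland) only;
counties without a single cultivated cell get a missing mean, never zero.
The working resolution is a config knob (synthetic default: 1 km cells),
since the appropriate resolution depends on the input land-use product.

## Gap statistics

`YGAP = Y̅S − Y̅FARM` (t ha⁻¹), `RYGAP = 100·YGAP/Y̅S` (%), and
`YGC = YGAP(end) − YGAP(start)`. Negative YGAP (farm yield above modeled
potential) is retained and logged rather than clipped — it flags model/data
inconsistency and should be visible. Sub-period YGCs telescope to the
full-period YGC because intermediate terms cancel pairwise; tests assert
the identity at 1e-9 absolute (float summation order prevents a bitwise
claim).

Gap magnitudes are binned with half-open `[lo, hi)` edges at
3/6/9/12 t ha⁻¹. Printed report tables show "3–6", "6–9" without stating
boundary ownership; lower-inclusive half-open intervals are the
deterministic convention adopted here. Gap changes are classed with a
sub-period scheme (−3/−2/−1/0/1) and a wider full-period scheme
(−6/−4/−2/0/2), labels L1…L6. Report ratios are rounded to 2 decimals;
machine outputs keep full precision.

## Spatial statistics

**Weights.** Queen contiguity (any shared boundary point), row-standardized,
built from the polygons with deterministic ordering by county id. Queen is
the common default for irregular county lattices; rook is exposed. Isolates
abort the run unless explicitly allowed.

**Gi\*.** The self-inclusive Getis–Ord statistic
`(Σⱼwᵢⱼxⱼ − x̄Wᵢ) / (S·√[(nΣⱼwᵢⱼ² − Wᵢ²)/(n−1)])` with `S` the population
standard deviation, classed hot/cold at |z| ≥ 1.65/1.96/2.58. "Hot-spot
analysis" in GIS practice denotes Gi\*; plain Gi is available by flag. In
the degenerate case where a neighborhood spans the whole study area the
statistic is 0/0 and defined as z = 0. No multiple-testing correction is
applied by default.

**Bivariate Moran's I / LISA.** `I_xy = Σᵢⱼ wᵢⱼ z_x,i z_y,j / S0` with
population-standardized scores; locals `Iᵢ = z_x,i · lagᵢ(z_y)` satisfy
`ΣᵢIᵢ/S0 = I` by construction. Inference is conditional permutation —
y shuffled over locations with x fixed; for locals, each county's neighbor
values are redrawn from the other n−1 locations. Pseudo-p =
(#(|null| ≥ |obs|)+1)/(n_perm+1), two-sided, n_perm = 999 by default with a
mandatory seed. LISA quadrant classes (HH/LL/HL/LH) are reported only where
the local pseudo-p ≤ α = 0.05. Both statistics are verified against naive
double-loop oracles at 1e-10 on small fixtures, and the permutation test's
type-I error is calibrated against the nominal α on exchangeable fields.

## Determinant ranking

Per period, YGC is regressed on the 27 candidate factors (4 climatic, 7
socioeconomic, 7 land-use, 9 human-investment) over counties that are not
municipal districts and have complete data; below 20 retained counties the
fit aborts as unreliable. The model is a `RandomForestRegressor` (default
1000 trees, full feature consideration, seeded). Importance is Breiman's
out-of-bag permutation importance, implemented here because scikit-learn
offers only held-out permutation and impurity flavors: per tree, the
increase in out-of-bag MSE when one factor's values are permuted, averaged
over trees. It is less biased toward high-cardinality variables than
impurity importance (kept as an option). Scores are `max(raw, 0)/max(raw)`
— the only simple map guaranteeing the [0, 1] range with the top factor at
exactly 1. The ten highest scores are key factors; ties at rank ten break
deterministically by factor name and are logged. Category contribution is
the percentage of top-ten slots per category, summing to 100 by
construction.

## Screening and the uplift scenario

Counties with final-epoch RYGAP **strictly** above 30 % are candidates
(boundary counties are excluded and logged); municipal districts are
removed because agriculture is not their main industry. The incremental
production of a +5 % uplift is `Σ sown_area · actual_yield · 0.05` over the
selected counties — the uplift applies to actual farm yield, not potential.

## Synthetic study region

The generator emulates the statistical structure the analysis assumes, not
any real province:

* **Counties**: an 11×11 grid of square counties (121 ≈ the 122 units of a
  typical provincial panel), 8×8 cells of 1 km each; a central 25-county
  block is flagged as municipal districts to exercise the exclusion rule.
* **Climate**: Q and T are Gaussian-smoothed white-noise fields (σ = 8
  cells) rescaled into (115, 145) kcal cm⁻² and (20, 26) °C with small
  per-epoch shifts. Smoothing of seeded noise was chosen over spectral
  synthesis — simpler, dependency-light, and it gives the positive spatial
  autocorrelation the spatial statistics need. These ranges put the
  region-mean YS in the 10–14 t ha⁻¹ band reported for humid subtropical
  double-cropping systems, which the tests assert.
* **Soil**: f(s) is a static smoothed field centred on 0.42 (spread ±0.08),
  clipped to (0, 1].  f(w) = 1 everywhere.
* **Land use**: a fine-grained (σ = 2 cells) suitability field thresholded
  at a per-epoch cultivated fraction (45–65 %), split into paddy (60–85 %
  of cultivated) and dryland; every county is guaranteed at least one
  cultivated cell, as real county units have.
* **Farm yields**: `yfarm = Y̅S · clip(base(epoch) + Σβ_v z_v + ε, 0.05, 0.95)`
  with the exploitation schedule (0.37, 0.55, 0.57, 0.51) — relative gaps
  near 63 % initially, strong narrowing in the first decade, partial
  re-widening at the end — planted effects on standardized covariates
  (defaults: GDPPC 0.06, SH 0.04, PCAI 0.03, REC 0.02) and ε ~ N(0, 0.02).
  Standardized covariates make the true importance ordering well-defined
  for recovery tests.
* **Panel**: terrain (DEM, Slope) static across epochs; socioeconomic and
  investment variables share a latent "development" factor trending upward
  over epochs, inducing realistic cross-correlations; marginal scales are
  pragmatic round numbers (the analysis standardizes covariates, so only
  ordering structure matters).

What the generator does **not** emulate: real climatology or station
interpolation, the full 25-class land-use legend, spatial autocorrelation
*within* the socioeconomic panel, measurement error in yearbook statistics,
or boundary changes over time. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not the empirical findings
one would obtain on real provincial data.

## Problem sizes and numerical choices

Tests run the full pipeline at 121 counties × 4 epochs; oracle-equivalence
fixtures stay at ≤ 25 counties where brute-force double loops are exact and
fast. The permutation-calibration study uses 500 replicates on a 36-county
grid at 199 permutations (the pseudo-p grid at 199 makes the nominal 5 %
level exactly attainable); the importance-recovery study uses 100 replicate
forests of 300 trees at n = 95 — forest size is a config parameter and 300
trees is ample for a 27-factor design of that size. Round-trip raster I/O
is asserted at ≤ 1e-9 relative error; weight rows sum to 1 within 1e-12;
spatial statistics match oracles at 1e-10.

## Known limitations

* Potential yield is an ideal ceiling, not the exploitable potential; the
  screening threshold partially accounts for the 15–25 % of the gap that is
  not exploitable in practice.
* One season-aggregate surface is computed; early/late rice are not modeled
  separately.
* Importance scores rank association, not causation, and carry no spatial
  mechanism.
* The raster pathway supports the text-based ASCII-grid format with square
  cells in one projected CRS per run; inputs in other CRSs are rejected
  rather than silently reprojected, and no resampling toolchain is
  included.
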