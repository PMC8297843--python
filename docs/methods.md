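# Methods

This document defines the statistical models, the synthetic-data
generator, the numerical choices, and the known limitations of the
package. Module references are to `habsel.<module>`.

## Data model

All spatial data live in one planar metric coordinate system (metres).
Rasters (`grids.Grid`) are regular square grids with `NaN` marking
missing cells; row 0 is the southernmost row; a cell covers a half-open
square so every point maps to exactly one cell. Raster I/O uses
plain-text ESRI ASCII grids and road networks use GeoJSON parsed with
shapely, so the package has no GDAL-stack dependency. A
`grids.LandscapeStack` is a set of co-registered layers (elevation,
slope, tpi, tri, canopy, road_density, categorical cover) plus a cover
codebook.

## Terrain covariates (`terrain`)

- **Slope** uses Horn's third-order finite difference on the 3×3
  neighbourhood, reported in degrees. Border cells and any cell whose
  neighbourhood contains a missing value are `NaN`
  (full-neighbourhood edge policy, applied to all window operators).
- **TRI** (terrain ruggedness) is the mean absolute elevation
  difference between the focal cell and its 8 neighbours.
- **TPI** (topographic position) is the focal elevation minus the mean
  of a square window of side ≈ `window_m` (default 1,000 m),
  **excluding the focal cell** from the mean; positive on ridges,
  negative in drainages. The window side is rounded to the nearest odd
  cell count (`window_cells`), minimum 3.
- **Road density** (km/km²) is total road length inside the moving
  square window divided by the window area. Because the window side is
  an odd cell count, the per-cell rasterized road length makes the
  window sum an exact geometric clip; window sums use an integral
  image, with a clamp at zero for few-ulp cancellation error.

All window operators are verified in the tests against brute-force
double-loop oracles to 1e-10 on random DEMs.

## Preprocessing (`preprocess`)

- **Movement filter.** For each consecutive pair of fixes per animal,
  the movement rate is distance / elapsed time; the location
  *preceding* a step slower than `min_rate_kmh` (default 0.025 km/h) is
  omitted. The filter is a single pass over the original step sequence:
  removals do not create and re-test merged steps, and the last fix
  (which precedes no step) is always kept. Consequently, if a track has
  `k` sub-threshold steps at non-adjacent positions, exactly `k`
  locations are omitted and counts are conserved exactly
  (`n_retained = n − k`).
- **Home ranges.** Bivariate-normal-kernel KDE with the reference
  bandwidth `h_ref = σ·n^(−1/6)`, `σ² = (var_x + var_y)/2`, evaluated
  on a 200×200 lattice padded 3·h_ref beyond the data. The 95% (or
  requested) isopleth polygon is the smallest superlevel set holding
  that probability mass, assembled from closed contour rings with holes
  honoured. At n = 10,000 points from an isotropic normal, the 95%
  area is within a few percent of the analytic `π·χ²₂,₀.₉₅·σ²` ellipse.
- **Availability.** Exactly `ratio` (default 5) available points per
  used point, sampled uniformly inside the animal's home-range polygon
  by rejection from its bounding box. The count is exact by
  construction; published datasets occasionally report available counts
  a fraction of a percent off the nominal ratio (pooled sampling,
  post-hoc drops), and this package deliberately does not reproduce
  such discrepancies.
- **Design table.** Used points outside their animal's home range are
  excluded (counted); rows whose cell has any missing covariate are
  dropped (counted). Continuous covariates are centred and scaled by
  the table's own mean/SD; categorical cover is dummy-coded against a
  reference level. The scaling dictionary is frozen into the fitted
  model so prediction on new rasters applies the training
  transformation.

## RSF model and selection algorithm (`rsf`)

The exponential RSF `w(x) = exp(β₁x₁ + … + βₚxₚ)` is estimated by
used–available logistic regression (statsmodels GLM/binomial, IRLS).
The intercept absorbs the used:available sampling ratio and is omitted
from prediction, so `w` is a *relative* selection strength. Perfect
separation is raised as `SeparationError` (the statsmodels
perfect-separation warning is converted to the error), rank deficiency
as `RankDeficiencyError` naming the aliased columns.

Model selection (`backward_select`, optionally preceded by
`pearson_screen`) runs three stages, every decision appended to a
replayable `SelectionLedger`:

1. **Correlation screen** — for each pair with |r| ≥ 0.5 (descending
   |r|), the member with the worse single-variable AIC is dropped.
2. **VIF screen** — variance inflation factors computed directly from
   the design (least-squares R² with intercept; VIF = ∞ for exact
   collinearity); terms above the threshold (default 5) dropped
   highest-first, dependents (interactions, quadratics) removed with
   their parents.
3. **CI backward elimination** — terms whose Wald confidence interval
   (default 95%) spans zero are removed one at a time (worst z first)
   provided removal does not increase AIC; an interaction whose CI
   excludes zero retains its parent main effects.

## Mixed model and functional response (`mixed`)

The across-pack analysis fits a binomial GLMM with fixed effects plus a
random intercept and an uncorrelated random road-density slope per
pack. No installed Python library provides a Laplace-approximate
binomial GLMM with random slopes, so the marginal likelihood is
implemented in-package: an inner 2-D Newton optimization of the
conditional modes per pack and an outer quasi-Newton (L-BFGS-B) over
the fixed effects and log-SDs. It was verified during development
against r-lme4 `glmer` on a simulated 8-pack dataset (fixed effects and
random-effect SDs agreeing to 4 decimals, log-likelihood to < 0.01); a
two-stage estimator (per-pack ML fits combined with DerSimonian–Laird
precision weighting) ships as a cross-check and fallback.

The **functional response** regresses per-pack road-selection odds
(`exp` of the per-pack road coefficient per 1 km/km², i.e. rescaled out
of the standardized units) on territory-mean road density by OLS,
reporting the slope, its CI/p-value, and the percent change in odds per
unit availability.

For *trend recovery*, the per-pack coefficients fed to the OLS are the
**unshrunk per-pack ML estimates** (`method="two-stage-unshrunk"`), not
the GLMM conditional modes: regressing shrunk (BLUP-like) group
estimates on a group-level covariate attenuates the trend toward zero,
which a 50-seed simulation confirmed (slope bias −0.048 and 86% CI
coverage for conditional modes versus −0.008 and 96% for unshrunk
estimates). The GLMM remains the inferential model for the variance
components and population-level road effect.

## Validation (`validate`)

- **Internal (k-fold).** Used points are split into k = 5 folds per
  animal. The model is refit on the training folds (same terms,
  training-fold scaling), the RSF surface is predicted over the study
  area, and its range is cut into `n_bins = 10` **equal-interval** bins
  spanning [min, max]. Per bin: *area* = number of raster cells;
  *area-adjusted frequency* = test-fold used count / cell count;
  zero-area bins are excluded. The statistic is the Spearman rank
  correlation between bin rank and area-adjusted frequency, averaged
  over folds. The *study area* must be the region actually available
  to the animals — the pipeline masks the landscape to the union of the
  KDE home ranges before validating (`pipeline.mask_to_home_ranges`);
  validating against a much larger raster makes the area adjustment
  meaningless. When using the standalone CLI, pass covariate rasters
  that cover the study area only.
- **External.** Out-of-sample used points are scored on a surface cut
  into **equal-area** deciles (stable sort of cells by predicted
  value), and the statistic is the Spearman correlation between decile
  rank and raw used frequency. Equal-area binning makes the statistic
  invariant to monotone transformations of the surface.
- Degenerate inputs (constant ranks on either side) return r_s = 0 with
  a `degenerate` flag rather than NaN.

**Top-bin sparsity.** Equal-interval bins on an `exp`-shaped surface
concentrate area in the low bins; the top bins may hold only a handful
of cells. With weak selection, the expected used count in those bins
per fold is < 3, so their area-adjusted frequencies are Poisson noise
and single-dataset internal r_s can be far below its multi-seed mean
(the README worked example shows 0.77 on one small dataset versus a
0.93 twenty-seed mean). This is a property of the binning definition,
not of the fitted model; the external equal-area statistic does not
exhibit it.

## Synthetic-data generator (`synthetic`) and experiments (`evaluation`)

`gen_landscape` builds correlated Gaussian-field terrain (elevation →
slope/TPI/TRI), canopy, categorical cover, and a random road network
rasterized to road density. `gen_tracks` samples used points for each
animal from `P(cell) ∝ exp(βᵀx)` restricted to the pack territory, with
timestamps on a fixed schedule, so the generating coefficients are known
exactly after availability normalization.

Experiment designs were frozen before their acceptance-scale runs, with
each parameter grounded in realistic field magnitudes rather than tuned
to outcomes:

- **Coverage** (`coverage_experiment`): 200 replicates of 6 animals ×
  2,000 used points (5:1 availability) from a four-term model; 95% Wald
  CI coverage of the generating (availability-normalized) coefficients
  is checked against 93–97%.
- **Validation self-consistency** (`validation_experiment`): two study
  areas on independent landscapes; a ruggedness-dominated generating
  model (raw β: tri 0.1, canopy 0.012, road −0.4; standardized
  magnitudes ≈ 0.6–0.8, 0.2, −0.2 — the dominant-terrain-axis strength
  typical of fitted carnivore RSFs). Internal 5-fold validation in the
  training area, external transfer to the second area, and a
  deliberately ruggedness-sign-flipped model as a negative control.
  A first design with several-fold weaker selection produced unstable
  internal statistics through the top-bin sparsity mechanism above and
  was replaced on realism grounds; development records retain the full
  analysis.
- **Functional-response recovery** (`funcresp_experiment`): 13 packs ×
  2,000 used points; per-pack road coefficients generated as
  `a + b·availability` with a = −0.5, b = 0.6, spanning roughly
  −0.5…+0.5 across the availability gradient (the spread seen in
  multi-pack field studies); candidate territories require mean road
  density ≥ 0.25 km/km² because a near-roadless territory has an
  unidentifiable road coefficient at the high-leverage end of the
  gradient. The unshrunk two-stage path (above) estimates the trend.

## Pipeline and reproducibility (`pipeline`, `cli`)

`RunConfig` (YAML) drives simulate → prep → fit → funcresp → validate.
Each stage's seed is `stage_seed(master, name)` — the first four bytes
of SHA-256 of `"master:name"`, reduced mod 2³¹ — so stages are
independently reproducible. A `manifest.json` records config, per-stage
parameters and timings, and the SHA-256 of every output file.

## Numerical choices

- Logistic fits: statsmodels IRLS, `maxiter=100`, `tol=1e-8`; Wald CIs
  with the normal quantile.
- Spearman: `scipy.stats.spearmanr` plus the degenerate-input
  convention above.
- KDE: own Gaussian-kernel evaluation on a padded lattice (kept
  dependency-light and exactly matching the documented h_ref).
- Laplace GLMM: inner Newton tolerance 1e-10 on the conditional modes;
  outer L-BFGS-B on (β, log σ); standard errors from the numerical
  Hessian of the marginal log-likelihood.
- All random draws use `numpy.random.default_rng`; every public
  stochastic function takes a seed or Generator.

## Limitations

- Planar coordinates only: no geographic CRS handling or reprojection;
  inputs must already share one metric CRS and grid.
- The movement filter is the single-pass variant; iterated refiltering
  of merged steps is deliberately out of scope.
- Availability is uniform within the KDE home range (third-order
  design); step-selection or second-order (landscape-level) designs are
  not implemented.
- The GLMM supports one grouping factor (pack) with a random intercept
  and one random slope, uncorrelated; general random-effect structures
  are out of scope.
- Internal validation inherits the equal-interval top-bin sparsity
  sensitivity described above; treat single-dataset internal r_s with
  that caveat and prefer the external equal-area statistic for model
  comparison.
- The synthetic landscape is a convenient stochastic caricature
  (Gaussian fields, disc territories); it is designed for estimator
  verification, not ecological realism of pattern.
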