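# habsel

Third-order (within-home-range) resource-selection-function (RSF) analysis
for GPS-collared wildlife, with a synthetic-data generator, a mixed-effects
functional-response analysis, and k-fold validation — plus an end-to-end,
manifest-tracked pipeline and CLI.

The package implements the common workflow for terrestrial carnivore
telemetry studies:

1. **Terrain covariates** — slope (Horn's method), topographic position
   index (TPI), terrain ruggedness index (TRI) and road density derived
   from a DEM and a road network, all on co-registered planar rasters
   (plain-text ESRI ASCII grids; no GDAL dependency).
2. **Preprocessing** — a movement-rate filter for stationary/duplicate
   fixes, Gaussian-KDE 95% home ranges (reference bandwidth), and a
   used–available design: 5 available points per used point drawn
   uniformly within each animal's home range, covariates extracted,
   continuous covariates centred and scaled with the scaling frozen into
   the fitted model.
3. **RSF fitting** — used–available logistic regression
   (`w(x) = exp(βᵀx)`, intercept omitted from prediction) with a
   sequential model-selection algorithm: pairwise-correlation screening
   (|r| ≥ 0.5, AIC decides which of a pair is kept), VIF screening,
   and backward elimination of terms whose confidence intervals span
   zero, with every decision recorded in a replayable selection ledger.
4. **Functional response** — a binomial GLMM (random intercept and
   random road-density slope per pack; in-package Laplace approximation,
   cross-checked against a two-stage meta-analytic estimator), then a
   regression of per-pack road-selection odds on territory-level road
   availability to test whether road selection strengthens where roads
   are more available.
5. **Validation** — k-fold internal validation with area-adjusted
   frequencies over equal-interval RSF bins (Spearman rank correlation
   per fold), and external validation on out-of-sample used points with
   equal-area RSF deciles.
6. **Synthetic data** — a landscape generator (correlated terrain,
   canopy, cover classes, road network) and a telemetry generator that
   samples used points from a known selection model within pack
   territories, so every estimator in the package can be tested against
   ground truth.

## Worked example

Simulate telemetry for one pack of two animals from a known selection
model, preprocess it, fit an RSF with the selection algorithm, and
validate it (`examples` below is a straight transcript — the output shown
is what the code prints):

```python
import numpy as np
import pandas as pd
from habsel import preprocess, rsf, synthetic, validate
from habsel.pipeline import mask_to_home_ranges

# 1. a synthetic 9 x 9 km landscape with terrain, cover and roads
landscape, roads = synthetic.gen_landscape(seed=7)

# 2. telemetry for one pack of two animals from a known selection model
truth = synthetic.TrueModel(
    terms=["slope", "tpi", "canopy", "road_density"],
    beta=[-0.05, -0.006, 0.008, -0.25])
pack = synthetic.PackSpec("pack01", territory_center=(4500.0, 4500.0),
                          territory_radius=2000.0, n_animals=2)
telemetry = synthetic.gen_tracks(
    landscape, [pack], truth,
    synthetic.SimConfig(seed=7, n_locations_per_animal=1500))
print(f"{len(telemetry)} fixes for {telemetry['animal_id'].nunique()} animals")

# 3. movement-rate filter and KDE home ranges
filtered, omitted = preprocess.movement_filter(telemetry)
print(f"movement filter omitted {omitted} fixes")

rng = np.random.default_rng(7)
home_ranges, avail = {}, []
for animal, sub in filtered.groupby("animal_id"):
    hr = preprocess.fit_kde_home_range(sub, isopleth=0.95)
    hr.animal_id = str(animal)
    home_ranges[str(animal)] = hr
    print(f"{animal}: 95% home range {hr.area_km2:.1f} km^2 "
          f"(h_ref {hr.h_ref:.0f} m)")
    inside = hr.contains(sub["x"].to_numpy(), sub["y"].to_numpy())
    av = preprocess.sample_available(hr, int(inside.sum()), ratio=5, seed=rng)
    av["animal_id"] = str(animal)
    av["pack_id"] = sub["pack_id"].iloc[0]
    av["study_area"] = sub["study_area"].iloc[0]
    avail.append(av)

table = preprocess.assemble_table(filtered, pd.concat(avail), landscape,
                                  home_ranges=home_ranges)
print(f"table: {table.n_used} used, {table.n_available} available")

# 4. fit an RSF with the sequential model-selection algorithm
model, ledger = rsf.backward_select(
    table, ["slope", "tpi", "tri", "canopy", "road_density"])
print("selected terms:", model.terms)
print(model.summary_frame().round(3))

# 5. internal 5-fold validation over the availability domain
#    (bin areas are counted over the union of the home ranges, not the
#    whole landscape, because that is what was available to the animals)
study_area = mask_to_home_ranges(landscape, home_ranges)
res = validate.internal_validate(model, table, study_area, k=5, seed=7)
print(f"internal validation mean r_s = {res.mean_rs:.3f}")
```

Output:

```
3000 fixes for 2 animals
movement filter omitted 4 fixes
pack01-a1: 95% home range 14.2 km^2 (h_ref 288 m)
pack01-a2: 95% home range 14.5 km^2 (h_ref 291 m)
table: 2996 used, 14980 available
selected terms: ['slope', 'tpi', 'canopy']
            beta     se  ci_lo  ci_hi
intercept -1.767  0.023 -1.812 -1.723
slope     -0.608  0.022 -0.652 -0.564
tpi       -0.338  0.021 -0.380 -0.297
canopy     0.153  0.020  0.113  0.193
internal validation mean r_s = 0.772
```

The recovered coefficients carry the generating signs and relative
magnitudes (the scaled slope coefficient −0.608 corresponds to the raw
−0.05 per degree; the weak road effect is dropped by the CI-screening
stage at this sample size).  The internal r_s of 0.772 is typical for a
single small dataset: equal-interval bins leave the highest-RSF bins with
few cells, so their area-adjusted frequencies are noisy — see
`docs/methods.md` for the multi-seed behaviour (mean r_s ≈ 0.93 in the
standard two-study-area experiment).

## Command-line interface

Every stage is also a `habsel` subcommand:

```
habsel terrain             derive slope/TPI/TRI/road-density rasters from a DEM
habsel simulate            synthetic landscape + telemetry from a YAML config
habsel prep                movement filter, KDE home ranges, used-available table
habsel fit                 RSF fitting with the selection algorithm + ledger
habsel predict             relative-selection surface for a fitted model
habsel funcresp            mixed-effects road functional response across packs
habsel validate-internal   k-fold area-adjusted internal validation
habsel validate-external   equal-area decile validation on held-out used points
habsel run                 full pipeline from a YAML run config (with manifest)
```

`habsel run --config run.yaml` executes simulate → prep → fit →
funcresp → validate with per-stage seeds derived deterministically from
one master seed, and writes a `manifest.json` with the SHA-256 of every
output, so runs are reproducible bit-for-bit.

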