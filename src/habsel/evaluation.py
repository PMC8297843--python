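"""Simulation experiments that exercise the full pipeline against known truth.

Three reusable experiment harnesses, shared by the test suite and the
reproduction script:

* :func:`coverage_experiment` — repeated parameter recovery: simulate
  used/available data from a known selection surface, fit the generating
  term set, and measure 95% CI coverage of the true (scaled)
  coefficients;
* :func:`validation_experiment` — self-consistency of the binned
  validation statistics: internal k-fold r_s for the generating model,
  external r_s when transferring the model to a second simulated area,
  and the external r_s of a ruggedness-sign-flipped model (which should
  rank habitat backwards);
* :func:`funcresp_experiment` — recovery of a road functional response
  whose per-pack coefficient is linear in territory road availability.

Problem sizes default to realistic summer GPS datasets (a few animals,
hundreds to thousands of fixes each) and are documented in the package's
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mixed, preprocess, rsf, synthetic, validate

__all__ = [
    "coverage_experiment",
    "validation_experiment",
    "funcresp_experiment",
    "DEFAULT_TRUE_MODEL",
]

#: default generating model: raw-scale coefficients giving paper-like
#: scaled magnitudes (avoid steep slopes and drainage bottoms, prefer
#: canopy, avoid roads)
DEFAULT_TRUE_MODEL = synthetic.TrueModel(
    terms=["slope", "tpi", "canopy", "road_density"],
    beta=[-0.05, -0.006, 0.008, -0.25],
    description="cursorial-predator style selection")


def _default_packs(landscape, n_packs: int, n_animals: int,
                   radius: float, rng: np.random.Generator
                   ) -> list[synthetic.PackSpec]:
    g = landscape.grid
    xmin, ymin, xmax, ymax = g.extent
    pad = radius + 2 * g.cell_size
    packs = []
    per = [n_animals // n_packs + (1 if i < n_animals % n_packs else 0)
           for i in range(n_packs)]
    for i in range(n_packs):
        packs.append(synthetic.PackSpec(
            pack_id=f"pack{i + 1:02d}",
            territory_center=(rng.uniform(xmin + pad, xmax - pad),
                              rng.uniform(ymin + pad, ymax - pad)),
            territory_radius=radius,
            n_animals=per[i]))
    return packs


def simulate_table(landscape, packs, true_model, seed: int,
                   n_used_per_animal: int, ratio: int = 5
                   ) -> preprocess.UsedAvailableTable:
    """Used points from the selection kernel + availability uniform over
    each pack's territory, assembled into a design table.

    Availability matches the generating distribution exactly, so fitting
    the generating terms estimates the true coefficients without
    home-range estimation error; the KDE/home-range path is exercised by
    the pipeline tests instead.
    """
    rng = np.random.default_rng(seed)
    telemetry = synthetic.gen_tracks(
        landscape, packs, true_model,
        synthetic.SimConfig(seed=int(rng.integers(2 ** 31)),
                            n_locations_per_animal=n_used_per_animal))
    avail = []
    for pack in packs:
        n_pack_used = n_used_per_animal * pack.n_animals
        av = synthetic.sample_territory_uniform(
            landscape, pack, ratio * n_pack_used, rng)
        av["animal_id"] = f"{pack.pack_id}-pooled"
        avail.append(av)
    available = pd.concat(avail, ignore_index=True)
    return preprocess.assemble_table(telemetry, available, landscape)


def true_scaled_beta(true_model: synthetic.TrueModel,
                     table: preprocess.UsedAvailableTable) -> dict[str, float]:
    """Generating coefficients on the table's centred/scaled scale."""
    out = {}
    for term, b in zip(true_model.terms, true_model.beta):
        if term in table.scaling:
            out[term] = b * table.scaling[term][1]
        else:
            out[term] = b
    return out


def mask_to_territories(landscape, packs) -> "synthetic.LandscapeStack":
    """Copy of the landscape with cells outside every territory missing.

    Validation statistics define bin areas over the region actually
    available to the animals; in the simulations that region is the
    union of pack territories.
    """
    from .grids import Grid, LandscapeStack

    g = landscape.grid
    mask = np.zeros((g.n_rows, g.n_cols), dtype=bool)
    for p in packs:
        rows, cols = synthetic.territory_cells(landscape,
                                               p.territory_center,
                                               p.territory_radius)
        mask[rows, cols] = True
    layers = {}
    for name, layer in landscape.layers.items():
        vals = layer.values.copy()
        vals[~mask] = np.nan
        layers[name] = Grid(vals, cell_size=g.cell_size, origin=g.origin)
    return LandscapeStack(layers=layers,
                          cover_codebook=dict(landscape.cover_codebook))


def coverage_experiment(n_replicates: int = 200, seed: int = 0,
                        n_animals: int = 6, n_used_per_animal: int = 2000,
                        true_model: synthetic.TrueModel | None = None
                        ) -> dict:
    """95% CI coverage of the generating coefficients over replicates.

    One landscape is generated once; each replicate redraws telemetry and
    availability, fits the generating term set, and checks whether each
    true (scaled) coefficient lies inside its 95% CI.  Returns the
    overall coverage fraction and per-term coverage.

    All animals share one territory so the pooled used-available logistic
    with a single intercept is exactly the generating contrast (separate
    territories would each need their own normalising intercept).
    """
    true_model = true_model or DEFAULT_TRUE_MODEL
    rng = np.random.default_rng(seed)
    landscape, _ = synthetic.gen_landscape(seed=int(rng.integers(2 ** 31)))
    packs = _default_packs(landscape, n_packs=1, n_animals=n_animals,
                           radius=2200.0, rng=rng)
    hits = {t: 0 for t in true_model.terms}
    for _ in range(n_replicates):
        table = simulate_table(landscape, packs, true_model,
                               seed=int(rng.integers(2 ** 31)),
                               n_used_per_animal=n_used_per_animal)
        model = rsf.fit_logistic(table, list(true_model.terms))
        truth = true_scaled_beta(true_model, table)
        ci = model.conf_int()
        for t in true_model.terms:
            lo, hi = ci[t]
            if lo <= truth[t] <= hi:
                hits[t] += 1
    per_term = {t: h / n_replicates for t, h in hits.items()}
    overall = float(np.mean(list(per_term.values())))
    return {"coverage": overall, "per_term": per_term,
            "n_replicates": n_replicates}


#: generating model for the validation experiments: terrain ruggedness is
#: the dominant axis of selection, mirroring an ambush predator.  Raw-scale
#: coefficients sized so the centred/scaled magnitudes (~0.7 ruggedness,
#: ~0.2 canopy, ~-0.2 roads) match the strength of selection that fitted
#: field RSFs report for their dominant terrain terms; much weaker
#: selection leaves the top equal-interval bins of the prediction surface
#: nearly unused (expected counts of a few points per fold), and the
#: binned validation statistic is then dominated by Poisson noise rather
#: than the model's ranking skill.
RUGGEDNESS_TRUE_MODEL = synthetic.TrueModel(
    terms=["tri", "canopy", "road_density"],
    beta=[0.1, 0.012, -0.4],
    description="ruggedness-dominated selection")


def validation_experiment(seed: int = 0, n_animals: int = 6,
                          n_used_per_animal: int = 2000,
                          k: int = 5, n_bins: int = 10) -> dict:
    """Internal, external and sign-flipped external validation statistics.

    Fits the generating model in a training area, then transfers it (and
    a copy with the ruggedness coefficient sign-flipped) to a second
    simulated area whose used points come from the same true model.
    """
    true_model = RUGGEDNESS_TRUE_MODEL
    rng = np.random.default_rng(seed)
    land_a, _ = synthetic.gen_landscape(seed=int(rng.integers(2 ** 31)))
    packs_a = _default_packs(land_a, 1, n_animals, 1800.0, rng)
    table = simulate_table(land_a, packs_a, true_model,
                           seed=int(rng.integers(2 ** 31)),
                           n_used_per_animal=n_used_per_animal)
    model = rsf.fit_logistic(table, list(true_model.terms))
    study_a = mask_to_territories(land_a, packs_a)
    internal = validate.internal_validate(model, table, study_a, k=k,
                                          n_bins=n_bins,
                                          seed=int(rng.integers(2 ** 31)))

    land_b, _ = synthetic.gen_landscape(seed=int(rng.integers(2 ** 31)))
    packs_b = _default_packs(land_b, 1, n_animals, 1800.0, rng)
    telemetry_b = synthetic.gen_tracks(
        land_b, packs_b, true_model,
        synthetic.SimConfig(seed=int(rng.integers(2 ** 31)),
                            n_locations_per_animal=n_used_per_animal))
    study_b = mask_to_territories(land_b, packs_b)
    external = validate.external_validate(model, telemetry_b, study_b,
                                          n_bins=n_bins)

    flipped = rsf.RSFModel(
        terms=model.terms,
        beta=np.array([b * (-1 if n == "tri" else 1)
                       for n, b in zip(model.names, model.beta)]),
        se=model.se, cov=model.cov, llf=model.llf, aic=model.aic,
        n_used=model.n_used, n_available=model.n_available,
        scaling=model.scaling, reference_level=model.reference_level,
        variant="sign-flipped")
    flipped_external = validate.external_validate(flipped, telemetry_b,
                                                  study_b, n_bins=n_bins)
    return {"internal_mean_rs": internal.mean_rs,
            "external_rs": external.mean_rs,
            "flipped_external_rs": flipped_external.mean_rs}


def funcresp_experiment(seed: int = 0, n_packs: int = 13,
                        n_used_per_pack: int = 2000,
                        a: float = -0.5, b: float = 0.6,
                        method: str = "two-stage-unshrunk",
                        min_mean_road_density: float = 0.25) -> dict:
    """One functional-response recovery run.

    Simulates packs whose true road coefficient rises linearly with
    territory road availability, runs the mixed-model + odds-trend
    analysis, and reports the estimated slope, its CI, and the true slope
    implied by the generating coefficients (the OLS slope of the true
    relative odds against availability).

    The defaults give per-pack road coefficients spanning roughly -0.5
    (road avoidance in road-poor territories) to +0.5 (road tolerance in
    road-rich ones) — the magnitude range reported for real wolf packs —
    so the between-pack signal the experiment must detect is comparable
    to field studies rather than vanishingly small.

    ``min_mean_road_density`` keeps near-roadless territories out of the
    scenario: a pack whose territory has almost no road variation has an
    unidentifiable road coefficient, and its noisy odds estimate sits at
    a high-leverage end of the availability gradient, so including it
    degrades the trend estimate rather than informing it.

    The default ``method`` regresses *unshrunk* per-pack estimates:
    conditional-mode (BLUP) shrinkage pulls extreme packs toward the
    mean, which systematically attenuates a between-pack trend, whereas
    unshrunk per-pack noise is mean-zero in the regression's response and
    is absorbed by the OLS residual variance.
    """
    rng = np.random.default_rng(seed)
    landscape, _ = synthetic.gen_landscape(seed=int(rng.integers(2 ** 31)),
                                           n_roads=16)
    telemetry, truth = synthetic.gen_functional_response_scenario(
        landscape, n_packs=n_packs, a=a, b=b,
        config=synthetic.SimConfig(seed=int(rng.integers(2 ** 31)),
                                   n_locations_per_animal=n_used_per_pack),
        min_mean_road_density=min_mean_road_density)
    avail = []
    for pid, sub in telemetry.groupby("pack_id"):
        row = truth[truth.pack_id == pid].iloc[0]
        pack = synthetic.PackSpec(
            pack_id=str(pid),
            territory_center=(row["center_x"], row["center_y"]),
            territory_radius=float(row["territory_radius"]))
        av = synthetic.sample_territory_uniform(landscape, pack,
                                                5 * len(sub), rng)
        av["animal_id"] = f"{pid}-pooled"
        avail.append(av)
    table = preprocess.assemble_table(
        telemetry, pd.concat(avail, ignore_index=True), landscape)
    mm = mixed.fit_mixed_logistic(
        table, ["slope", "tpi", "road_density"], method=method)
    odds = mixed.pack_road_odds(mm)
    availability = truth.set_index("pack_id")["mean_road_density"]
    fr = mixed.functional_response(odds, availability)

    true_odds = pd.Series(np.exp(truth["true_road_beta"].to_numpy()),
                          index=truth["pack_id"])
    true_fr = mixed.functional_response(true_odds, availability)
    return {"slope": fr.slope, "ci": fr.ci, "p_value": fr.p_value,
            "percent_change_per_unit": fr.percent_change_per_unit,
            "true_slope": true_fr.slope,
            "slope_positive": fr.slope > 0,
            "ci_covers_truth": fr.ci[0] <= true_fr.slope <= fr.ci[1]}
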