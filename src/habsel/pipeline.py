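"""End-to-end pipeline: simulate -> prep -> fit -> funcresp -> validate.

A single :class:`RunConfig` (YAML-serializable) drives the whole run; a
JSON manifest records every input hash, stage parameter, derived seed and
output path so a run can be reproduced bit-for-bit.  Each stage gets its
own seed derived deterministically from the top-level seed and the stage
name, so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed",
           "mask_to_home_ranges"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    # simulation
    simulate: bool = True
    extent_m: tuple[float, float] = (9000.0, 9000.0)
    cell_size: float = 30.0
    n_packs: int = 4
    n_animals_per_pack: int = 2
    n_locations_per_animal: int = 400
    territory_radius_m: float = 1800.0
    true_terms: list[str] = field(
        default_factory=lambda: ["slope", "tpi", "canopy", "road_density"])
    true_beta: list[float] = field(
        default_factory=lambda: [-0.05, -0.006, 0.008, -0.25])
    # external inputs (used when simulate is False)
    telemetry_csv: str | None = None
    covariate_dir: str | None = None
    # preprocessing
    isopleth: float = 0.95
    ratio: int = 5
    min_rate_kmh: float = 0.025
    apply_movement_filter: bool = True
    # model
    reference_level: str = "conifer"
    global_terms: list[str] | None = None
    r_threshold: float = 0.5
    vif_threshold: float = 5.0
    ci_level: float = 0.95
    variant: str = "custom"
    # validation / functional response
    k_folds: int = 5
    n_bins: int = 10
    run_funcresp: bool = True
    run_validation: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "extent_m" in d:
            d["extent_m"] = tuple(d["extent_m"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def mask_to_home_ranges(landscape, home_ranges):
    """Copy of the landscape with cells outside every home range missing.

    Internal validation defines bin areas over the region actually
    available to the animals, i.e. the union of their home ranges.
    """
    from .grids import Grid, LandscapeStack

    g = landscape.grid
    xx, yy = np.meshgrid(g.x_centers(), g.y_centers())
    mask = np.zeros((g.n_rows, g.n_cols), dtype=bool)
    for hr in home_ranges.values():
        mask |= hr.contains(xx.ravel(), yy.ravel()).reshape(mask.shape)
    layers = {}
    for name, layer in landscape.layers.items():
        vals = layer.values.copy()
        vals[~mask] = np.nan
        layers[name] = Grid(vals, cell_size=g.cell_size, origin=g.origin)
    return LandscapeStack(layers=layers,
                          cover_codebook=dict(landscape.cover_codebook))


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in order and return the run manifest."""
    from . import mixed, preprocess, rsf, synthetic, validate
    from .grids import LandscapeStack

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}
    manifest_path = out / "manifest.json"

    def persist() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path),
                                     "sha256": _sha256(path)}

    try:
        # ---- simulate or load -------------------------------------------
        t0 = time.time()
        if config.simulate:
            sim_seed = stage_seed(config.seed, "simulate")
            landscape, roads = synthetic.gen_landscape(
                extent_m=config.extent_m, cell_size=config.cell_size,
                seed=sim_seed)
            model_true = synthetic.TrueModel(
                terms=list(config.true_terms), beta=list(config.true_beta),
                description="pipeline truth")
            rng = np.random.default_rng(sim_seed)
            g = landscape.grid
            xmin, ymin, xmax, ymax = g.extent
            pad = config.territory_radius_m + 2 * g.cell_size
            packs = [
                synthetic.PackSpec(
                    pack_id=f"pack{i + 1:02d}",
                    territory_center=(rng.uniform(xmin + pad, xmax - pad),
                                      rng.uniform(ymin + pad, ymax - pad)),
                    territory_radius=config.territory_radius_m,
                    n_animals=config.n_animals_per_pack)
                for i in range(config.n_packs)
            ]
            telemetry = synthetic.gen_tracks(
                landscape, packs, model_true,
                synthetic.SimConfig(
                    seed=sim_seed,
                    n_locations_per_animal=config.n_locations_per_animal))
            cov_dir = out / "covs"
            landscape.write_dir(cov_dir)
            roads.to_geojson(out / "roads.geojson")
            telemetry.to_csv(out / "telemetry.csv", index=False)
            record("roads", out / "roads.geojson")
            record("telemetry", out / "telemetry.csv")
            for p in sorted(cov_dir.iterdir()):
                record(f"covs/{p.name}", p)
        else:
            if not config.telemetry_csv or not config.covariate_dir:
                raise ValueError("telemetry_csv and covariate_dir required "
                                 "when simulate is disabled")
            telemetry = pd.read_csv(config.telemetry_csv,
                                    parse_dates=["timestamp"])
            landscape = LandscapeStack.read_dir(config.covariate_dir)
        manifest["stages"]["simulate"] = {
            "enabled": config.simulate, "seconds": time.time() - t0,
            "n_locations": len(telemetry)}
        persist()

        # ---- preprocess -------------------------------------------------
        t0 = time.time()
        if config.apply_movement_filter:
            filtered, omitted = preprocess.movement_filter(
                telemetry, config.min_rate_kmh)
        else:
            filtered, omitted = telemetry, 0
        prep_seed = stage_seed(config.seed, "prep")
        rng = np.random.default_rng(prep_seed)
        home_ranges, avail_frames = {}, []
        for animal, sub in filtered.groupby("animal_id"):
            hr = preprocess.fit_kde_home_range(sub, config.isopleth)
            hr.animal_id = str(animal)
            home_ranges[str(animal)] = hr
            inside = hr.contains(sub["x"].to_numpy(), sub["y"].to_numpy())
            n_in = int(inside.sum())
            if n_in == 0:
                continue
            av = preprocess.sample_available(hr, n_in, config.ratio, rng)
            av["animal_id"] = str(animal)
            av["pack_id"] = sub["pack_id"].iloc[0]
            av["study_area"] = sub["study_area"].iloc[0]
            avail_frames.append(av)
        available = pd.concat(avail_frames, ignore_index=True)
        table = preprocess.assemble_table(
            filtered, available, landscape,
            reference_level=config.reference_level, home_ranges=home_ranges)
        table.df.to_csv(out / "table.csv", index=False)
        with open(out / "scaling.json", "w") as fh:
            json.dump(table.scaling_to_json(), fh, indent=1)
        record("table", out / "table.csv")
        record("scaling", out / "scaling.json")
        manifest["stages"]["prep"] = {
            "seconds": time.time() - t0, "omitted_by_filter": omitted,
            "n_used": table.n_used, "n_available": table.n_available,
            "n_dropped": table.n_dropped_missing, "seed": prep_seed}
        persist()

        # ---- fit --------------------------------------------------------
        t0 = time.time()
        global_terms = config.global_terms
        if global_terms is None:
            global_terms = [t for t in
                            ("slope", "tpi", "tri", "canopy", "road_density")
                            if t in table.df]
            global_terms += [f"cover_{lv}" for lv in table.cover_levels]
        candidates = [t for t in global_terms
                      if ":" not in t and not t.endswith("^2")]
        retained, ledger = rsf.pearson_screen(table, candidates,
                                              config.r_threshold)
        kept = [t for t in global_terms
                if t in retained
                or (":" in t and all(u in retained for u in t.split(":")))
                or (t.endswith("^2") and t[:-2] in retained)]
        model, ledger = rsf.backward_select(
            table, kept, vif_threshold=config.vif_threshold,
            ci_level=config.ci_level, variant=config.variant, ledger=ledger)
        model.to_json(out / "model.json")
        ledger.to_csv(out / "ledger.csv")
        record("model", out / "model.json")
        record("ledger", out / "ledger.csv")
        surface = rsf.predict_rsf(model, landscape)
        from .grids import write_ascii_grid
        write_ascii_grid(surface, out / "rsf_surface.asc")
        record("rsf_surface", out / "rsf_surface.asc")
        manifest["stages"]["fit"] = {
            "seconds": time.time() - t0, "terms": model.terms,
            "aic": model.aic}
        persist()

        # ---- functional response ---------------------------------------
        t0 = time.time()
        if config.run_funcresp and table.df["pack_id"].nunique() >= 3:
            fixed = list(model.terms)
            if "road_density" not in fixed:
                fixed.append("road_density")
            mm = mixed.fit_mixed_logistic(table, fixed)
            odds = mixed.pack_road_odds(mm)
            avail = mixed.territory_mean_road_density(
                landscape, home_ranges=home_ranges, table=table)
            fr = mixed.functional_response(odds, avail.loc[odds.index])
            fr.per_pack.to_csv(out / "functional_response.csv", index=False)
            with open(out / "functional_response.json", "w") as fh:
                json.dump(fr.to_json_dict(), fh, indent=1)
            mixed.plot_functional_response(fr, out / "functional_response.svg")
            record("functional_response", out / "functional_response.csv")
            record("functional_response_json",
                   out / "functional_response.json")
            record("functional_response_plot",
                   out / "functional_response.svg")
            manifest["stages"]["funcresp"] = {
                "seconds": time.time() - t0,
                "slope": fr.slope, "p_value": fr.p_value,
                "percent_change_per_unit": fr.percent_change_per_unit}
        else:
            manifest["stages"]["funcresp"] = {"skipped": True}
        persist()

        # ---- validation -------------------------------------------------
        t0 = time.time()
        if config.run_validation:
            val_seed = stage_seed(config.seed, "validate")
            # the study area for bin-area accounting is the region actually
            # available to the animals: the union of their home ranges
            study_area = mask_to_home_ranges(landscape, home_ranges)
            res = validate.internal_validate(
                model, table, study_area, k=config.k_folds,
                n_bins=config.n_bins, seed=val_seed)
            res.to_frame().to_csv(out / "internal_validation.csv",
                                  index=False)
            validate.plot_validation(res, out / "internal_validation.svg")
            record("internal_validation", out / "internal_validation.csv")
            record("internal_validation_plot",
                   out / "internal_validation.svg")
            manifest["stages"]["validate"] = {
                "seconds": time.time() - t0, "mean_rs": res.mean_rs,
                "seed": val_seed}
        else:
            manifest["stages"]["validate"] = {"skipped": True}
        persist()
    except Exception:
        persist()  # manifest-so-far survives a failed stage
        raise
    return manifest
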