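"""Synthetic landscapes and multi-pack telemetry from a known selection surface.

The generator produces the two inputs every downstream stage needs —
a co-registered covariate raster stack and GPS-like point tracks — from a
*known* true selection model, so parameter recovery, validation behaviour
and the functional-response analysis can all be tested against ground
truth.

Generative model
----------------
Each animal's used locations are independent weighted draws from the grid
cells inside its pack's circular territory, with cell weight proportional
to ``exp(sum_k beta_k * x_k(cell))`` — exactly the exponential form a
third-order used-available logistic RSF estimates.  Draws are jittered
uniformly within the 30 m cell and stamped at the pack's fix interval
(4-13 h).  A configurable fraction of consecutive fixes is replaced by
near-stationary rendezvous-site clusters (steps < 100 m), and Gaussian
location error (e.g. 150-200 m, emulating VHF triangulation) can be added
after the fact.

The simulator is *not* a movement model: draws are independent given the
territory, which matches the estimand of a used-available RSF and keeps
recovery tests clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from . import terrain
from .grids import DEFAULT_CODEBOOK, Grid, LandscapeStack, RoadNetwork

__all__ = [
    "TrueModel",
    "PackSpec",
    "SimConfig",
    "gen_landscape",
    "gen_tracks",
    "gen_functional_response_scenario",
]


@dataclass
class TrueModel:
    """True selection coefficients on the raw covariate scale.

    ``terms`` may name continuous layers ("slope", "tri", ...), cover
    classes ("cover_burn"), pairwise interactions ("road_density:canopy")
    or a quadratic ("tri^2").
    """

    terms: list[str]
    beta: list[float]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.beta):
            raise ValueError("one coefficient per term required")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, self.beta))


@dataclass
class PackSpec:
    pack_id: str
    territory_center: tuple[float, float]
    territory_radius: float  # m
    n_animals: int = 1
    fix_interval_h: float = 4.0
    rendezvous_fraction: float = 0.0
    road_beta_override: float | None = None
    study_area: str = "sim"

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 4.0 <= self.fix_interval_h <= 13.0:
            raise ValueError("fix_interval_h must lie in [4, 13] hours")
        if not 0.0 <= self.rendezvous_fraction < 1.0:
            raise ValueError("rendezvous_fraction must lie in [0, 1)")


@dataclass
class SimConfig:
    seed: int = 0
    n_locations_per_animal: int = 200
    location_error_sd: float = 0.0  # m; 150-200 emulates VHF accuracy
    start_time: str = "2017-06-01T00:00:00"

    def __post_init__(self) -> None:
        if self.n_locations_per_animal < 2:
            raise ValueError("need at least 2 locations per animal")


# ---------------------------------------------------------------------------
# landscape generation

def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance Gaussian random field via smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells,
                                mode="reflect")
    return (f - f.mean()) / f.std()


def _gen_roads(rng: np.random.Generator, dem: Grid, slope: Grid,
               n_roads: int) -> RoadNetwork:
    """Random polylines biased toward low-slope terrain.

    Each road is a persistent random walk whose heading is nudged toward
    the lowest-slope of a few candidate directions.
    """
    xmin, ymin, xmax, ymax = dem.extent
    step = 4 * dem.cell_size
    lines = []
    slope_vals = np.nan_to_num(slope.values, nan=90.0)
    for _ in range(n_roads):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        heading = rng.uniform(0, 2 * np.pi)
        pts = [(x, y)]
        for _ in range(rng.integers(20, 60)):
            cands = heading + rng.uniform(-0.6, 0.6, size=5)
            best, best_s = None, np.inf
            for h in cands:
                nx, ny = x + step * np.cos(h), y + step * np.sin(h)
                r, c = dem.cell_index(nx, ny)
                s = slope_vals[r, c] if r >= 0 else np.inf
                if s < best_s:
                    best, best_s = (nx, ny, h), s
            if best is None or not np.isfinite(best_s):
                break
            x, y, heading = best
            pts.append((x, y))
        if len(pts) >= 2:
            lines.append(LineString(pts))
    classes = ["paved" if rng.random() < 0.2 else "unpaved" for _ in lines]
    return RoadNetwork(polylines=lines, road_class=classes)


def gen_landscape(extent_m: tuple[float, float] = (9000.0, 9000.0),
                  cell_size: float = 30.0,
                  seed: int = 0,
                  n_roads: int = 12,
                  relief_m: float = 250.0,
                  base_elevation_m: float = 1400.0,
                  tpi_window_m: float = 1000.0,
                  road_window_m: float = 1000.0,
                  ) -> tuple[LandscapeStack, RoadNetwork]:
    """A mountain-foothills style landscape with all covariate layers.

    The DEM is a smoothed Gaussian random field (relief ~ ``relief_m``);
    slope/TPI/TRI are derived from it, canopy and cover come from
    correlated random fields, and roads are low-slope-seeking polylines
    rasterized to a density layer.
    """
    width, height = extent_m
    if width < 3000 or height < 3000:
        raise ValueError("extent must be at least 3x3 km for the TPI window")
    n_cols = int(round(width / cell_size))
    n_rows = int(round(height / cell_size))
    rng = np.random.default_rng(seed)

    rough = _smooth_field(rng, (n_rows, n_cols), sigma_cells=3.0)
    broad = _smooth_field(rng, (n_rows, n_cols), sigma_cells=12.0)
    dem_vals = base_elevation_m + relief_m * (0.8 * broad + 0.16 * rough)
    dem = Grid(values=dem_vals, cell_size=cell_size)

    derived = terrain.derive_all(dem, tpi_window_m=tpi_window_m)

    canopy_field = _smooth_field(rng, (n_rows, n_cols), sigma_cells=6.0)
    # canopy loosely tracks elevation (conifer belt), bounded to [0, 100]
    canopy = 100.0 / (1.0 + np.exp(-(0.8 * canopy_field + 0.4 * broad)))
    canopy = np.clip(canopy, 0.0, 100.0)

    cover_field = _smooth_field(rng, (n_rows, n_cols), sigma_cells=8.0)
    cover_field2 = _smooth_field(rng, (n_rows, n_cols), sigma_cells=5.0)
    cover = np.zeros((n_rows, n_cols))             # conifer by default
    cover[cover_field > 0.9] = 1                   # grass-shrub patches
    cover[cover_field2 > 1.3] = 2                  # burns
    cover[(cover_field < -1.1) & (cover_field2 < 0)] = 3   # logged
    cover[np.abs(broad) < 0.03] = 4                # riparian strings
    cover[cover_field2 < -1.7] = 5                 # other

    roads = _gen_roads(rng, dem, derived["slope"], n_roads)
    road_density = terrain.derive_road_density(roads, dem, road_window_m)

    stack = LandscapeStack(
        layers={
            **derived,
            "canopy": Grid(canopy, cell_size=cell_size),
            "cover": Grid(cover, cell_size=cell_size),
            "road_density": road_density,
        },
        cover_codebook=dict(DEFAULT_CODEBOOK),
    )
    return stack, roads


# ---------------------------------------------------------------------------
# covariate evaluation on the raw scale

def _term_values(landscape: LandscapeStack, term: str,
                 rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Raw-scale value of one model term at given cells."""
    if ":" in term:
        a, b = term.split(":")
        return (_term_values(landscape, a, rows, cols)
                * _term_values(landscape, b, rows, cols))
    if term.endswith("^2"):
        base = _term_values(landscape, term[:-2], rows, cols)
        return base ** 2
    if term.startswith("cover_"):
        label = term[len("cover_"):]
        codes = {v: k for k, v in landscape.cover_codebook.items()}
        if label not in codes:
            raise ValueError(f"cover class {label!r} not in codebook")
        return (landscape["cover"].values[rows, cols] == codes[label]).astype(float)
    if term not in landscape:
        raise ValueError(f"term {term!r} names no landscape layer")
    return landscape[term].values[rows, cols]


def territory_cells(landscape: LandscapeStack, center: tuple[float, float],
                    radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Cells whose centres lie within ``radius - cell_size`` of the centre
    and carry no missing covariate (so a within-cell jitter stays inside
    the territory)."""
    g = landscape.grid
    xc = g.x_centers()
    yc = g.y_centers()
    xx, yy = np.meshgrid(xc, yc)
    inside = np.hypot(xx - center[0], yy - center[1]) <= radius - g.cell_size
    finite = np.ones_like(inside)
    for name, layer in landscape.layers.items():
        finite &= np.isfinite(layer.values)
    rows, cols = np.nonzero(inside & finite)
    return rows, cols


def _linear_predictor(landscape: LandscapeStack, model: TrueModel,
                      rows: np.ndarray, cols: np.ndarray,
                      road_beta_override: float | None = None) -> np.ndarray:
    eta = np.zeros(len(rows))
    for term, beta in zip(model.terms, model.beta):
        if term == "road_density" and road_beta_override is not None:
            beta = road_beta_override
        eta += beta * _term_values(landscape, term, rows, cols)
    return eta


def gen_tracks(landscape: LandscapeStack, packs: list[PackSpec],
               model: TrueModel, config: SimConfig) -> pd.DataFrame:
    """Telemetry for all packs: one row per fix.

    Columns: animal_id, pack_id, study_area, timestamp, x, y.
    """
    rng = np.random.default_rng(config.seed)
    g = landscape.grid
    start = pd.Timestamp(config.start_time)
    frames = []
    for pack in packs:
        rows, cols = territory_cells(landscape, pack.territory_center,
                                     pack.territory_radius)
        if len(rows) == 0:
            raise ValueError(
                f"territory of pack {pack.pack_id!r} contains no usable cells")
        eta = _linear_predictor(landscape, model, rows, cols,
                                pack.road_beta_override)
        w = np.exp(eta - eta.max())
        p = w / w.sum()
        n = config.n_locations_per_animal
        for a in range(pack.n_animals):
            animal_id = f"{pack.pack_id}-a{a + 1}"
            idx = rng.choice(len(rows), size=n, p=p)
            x = (g.origin[0] + (cols[idx] + rng.uniform(0, 1, n)) * g.cell_size)
            y = (g.origin[1] + (rows[idx] + rng.uniform(0, 1, n)) * g.cell_size)
            if pack.rendezvous_fraction > 0:
                x, y = _insert_rendezvous(rng, x, y, pack.rendezvous_fraction)
            if config.location_error_sd > 0:
                x = x + rng.normal(0, config.location_error_sd, n)
                y = y + rng.normal(0, config.location_error_sd, n)
            ts = start + pd.to_timedelta(
                np.arange(n) * pack.fix_interval_h, unit="h")
            frames.append(pd.DataFrame({
                "animal_id": animal_id,
                "pack_id": pack.pack_id,
                "study_area": pack.study_area,
                "timestamp": ts,
                "x": x,
                "y": y,
            }))
    return pd.concat(frames, ignore_index=True)


def _insert_rendezvous(rng: np.random.Generator, x: np.ndarray, y: np.ndarray,
                       fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Replace blocks of consecutive fixes by near-stationary clusters.

    Blocks never overlap and are placed until at least ``fraction`` of the
    consecutive steps are within-cluster; cluster spread is < 25 m so
    those steps stay well under 100 m.
    """
    n = len(x)
    target_steps = int(round(fraction * (n - 1)))
    if target_steps < 1 or n < 3:
        return x, y
    x, y = x.copy(), y.copy()
    occupied = np.zeros(n, dtype=bool)
    short_steps = 0
    attempts = 0
    while short_steps < target_steps and attempts < 50 * n:
        attempts += 1
        block = max(2, min(int(rng.integers(4, 12)),
                           target_steps - short_steps + 1))
        start = int(rng.integers(0, n - block + 1))
        if occupied[start:start + block].any():
            continue
        cx, cy = x[start], y[start]
        x[start:start + block] = cx + rng.uniform(-12, 12, block)
        y[start:start + block] = cy + rng.uniform(-12, 12, block)
        occupied[start:start + block] = True
        short_steps += block - 1
    return x, y


def sample_territory_uniform(landscape: LandscapeStack, pack: PackSpec,
                             n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform points over a pack's territory cells (jittered within cell).

    This is the generating availability distribution, handy when a test
    wants the availability sample to match the simulator exactly instead
    of an estimated home range.
    """
    g = landscape.grid
    rows, cols = territory_cells(landscape, pack.territory_center,
                                 pack.territory_radius)
    if len(rows) == 0:
        raise ValueError(
            f"territory of pack {pack.pack_id!r} contains no usable cells")
    idx = rng.integers(0, len(rows), n)
    x = g.origin[0] + (cols[idx] + rng.uniform(0, 1, n)) * g.cell_size
    y = g.origin[1] + (rows[idx] + rng.uniform(0, 1, n)) * g.cell_size
    return pd.DataFrame({"x": x, "y": y, "pack_id": pack.pack_id,
                         "study_area": pack.study_area})


def gen_functional_response_scenario(
        landscape: LandscapeStack,
        n_packs: int,
        a: float,
        b: float,
        config: SimConfig,
        base_model: TrueModel | None = None,
        territory_radius: float = 1500.0,
        n_animals_per_pack: int = 1,
        min_mean_road_density: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Telemetry where each pack's road coefficient tracks road availability.

    Pack *p*'s true (raw-scale) road-density coefficient is
    ``a + b * mean road density over p's territory``, producing a linear
    functional response whose slope the analysis should recover.  Returns
    the telemetry and a per-pack truth table
    (pack_id, mean_road_density, true_road_beta).

    Candidate territories with mean road density below
    ``min_mean_road_density`` are excluded: a road-selection coefficient
    is not identifiable for a pack whose territory contains no roads, so
    such packs would contribute nothing but noise to the analysis.
    """
    if n_packs < 4:
        raise ValueError("need at least 4 packs for a road gradient")
    rng = np.random.default_rng(config.seed)
    g = landscape.grid
    if base_model is None:
        base_model = TrueModel(
            terms=["slope", "tpi", "road_density"],
            beta=[-0.05, -0.02, 0.0],
            description="baseline terrain selection; road beta set per pack")
    elif "road_density" not in base_model.terms:
        raise ValueError("base model must include a road_density term")

    # place candidate territories, then keep a set spanning the road gradient
    xmin, ymin, xmax, ymax = g.extent
    pad = territory_radius + 2 * g.cell_size
    candidates = []
    for _ in range(400):
        cx = rng.uniform(xmin + pad, xmax - pad)
        cy = rng.uniform(ymin + pad, ymax - pad)
        rows, cols = territory_cells(landscape, (cx, cy), territory_radius)
        if len(rows) == 0:
            continue
        mean_rd = float(landscape["road_density"].values[rows, cols].mean())
        if mean_rd < min_mean_road_density:
            continue
        candidates.append((cx, cy, mean_rd))
        if len(candidates) >= 8 * n_packs:
            break
    if len(candidates) < n_packs:
        raise ValueError("could not place enough territories with roads; "
                         "lower min_mean_road_density or add roads")
    candidates.sort(key=lambda t: t[2])
    if candidates[-1][2] - candidates[0][2] < 1e-9:
        raise ValueError("degenerate road gradient: all territory means equal")
    # spread picks evenly across the availability gradient
    pick = np.linspace(0, len(candidates) - 1, n_packs).round().astype(int)

    packs, truth_rows = [], []
    for i, ci in enumerate(pick):
        cx, cy, mean_rd = candidates[ci]
        true_beta = a + b * mean_rd
        packs.append(PackSpec(
            pack_id=f"pack{i + 1:02d}",
            territory_center=(cx, cy),
            territory_radius=territory_radius,
            n_animals=n_animals_per_pack,
            fix_interval_h=4.0,
            road_beta_override=true_beta,
        ))
        truth_rows.append({"pack_id": f"pack{i + 1:02d}",
                           "mean_road_density": mean_rd,
                           "true_road_beta": true_beta,
                           "center_x": cx, "center_y": cy,
                           "territory_radius": territory_radius})
    telemetry = gen_tracks(landscape, packs, base_model, config)
    return telemetry, pd.DataFrame(truth_rows)
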