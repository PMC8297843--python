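"""Telemetry preprocessing: movement filter, KDE home ranges, the
used-available design table.

The pipeline mirrors the standard third-order RSF workflow:

1. drop near-stationary fixes (movement rate < 0.025 km/h, i.e. steps
   < 100 m in 4 h) so the used sample reflects travelling/hunting
   behaviour rather than rendezvous-site loitering;
2. estimate per-animal kernel density home ranges (bivariate normal
   kernel, reference bandwidth ``href = sigma * n^(-1/6)``) and take the
   95% (or 99%) isopleth polygon;
3. keep used fixes inside the animal's home range and draw 5 available
   points per used point uniformly within it;
4. extract covariates at each point's grid cell, centre and scale the
   continuous ones, and expand cover classes to indicators against a
   reference level (conifer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely import contains_xy
from shapely.ops import unary_union
from skimage import measure

from .grids import CONTINUOUS_LAYERS, LandscapeStack

logger = logging.getLogger(__name__)

__all__ = [
    "movement_filter",
    "fit_kde_home_range",
    "sample_available",
    "assemble_table",
    "HomeRange",
    "UsedAvailableTable",
]


# ---------------------------------------------------------------------------
# movement-rate filter

def movement_filter(track: pd.DataFrame, min_rate_kmh: float = 0.025
                    ) -> tuple[pd.DataFrame, int]:
    """Drop locations preceding sub-threshold steps; single pass per animal.

    For each consecutive pair of fixes the movement rate is
    distance / elapsed time; the location *preceding* a step slower than
    ``min_rate_kmh`` is removed.  The pass evaluates the original step
    sequence only — removals do not create and re-test merged steps — and
    the last fix of each animal (which precedes no step) is always kept.

    Returns the filtered track and the number of omitted locations.
    """
    frames = []
    omitted = 0
    for animal, sub in track.groupby("animal_id", sort=False):
        sub = sub.reset_index(drop=True)
        if len(sub) < 2:
            frames.append(sub)
            continue
        t = pd.to_datetime(sub["timestamp"]).to_numpy()
        dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
        if np.any(dt_h <= 0):
            i = int(np.argmax(dt_h <= 0))
            raise ValueError(
                f"non-increasing timestamps for animal {animal!r} at "
                f"{sub['timestamp'].iloc[i + 1]}")
        dist_km = np.hypot(np.diff(sub["x"].to_numpy()),
                           np.diff(sub["y"].to_numpy())) / 1000.0
        rate = dist_km / dt_h
        keep = np.append(rate >= min_rate_kmh, True)  # final fix retained
        omitted += int((~keep).sum())
        frames.append(sub.loc[keep])
    out = pd.concat(frames, ignore_index=True)
    return out, omitted


# ---------------------------------------------------------------------------
# KDE home range

@dataclass
class HomeRange:
    animal_id: str
    isopleth: float
    polygon: MultiPolygon
    area_km2: float
    h_ref: float

    def contains(self, x, y) -> np.ndarray:
        return contains_xy(self.polygon, x, y)


def _rings_to_multipolygon(rings: list[np.ndarray]) -> MultiPolygon:
    """Assemble closed contour rings into polygons with holes.

    A ring contained in an odd number of other rings is a hole of its
    smallest enclosing shell.
    """
    polys = [Polygon(r) for r in rings if len(r) >= 4]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    polys = [p for p in polys if not p.is_empty and p.area > 0]
    polys.sort(key=lambda p: p.area, reverse=True)
    shells: list[Polygon] = []
    holes: list[tuple[int, Polygon]] = []
    for p in polys:
        depth = sum(1 for q in polys
                    if q.area > p.area and q.contains(p.representative_point()))
        if depth % 2 == 0:
            shells.append(p)
        else:
            parent = min(
                (i for i, s in enumerate(shells)
                 if s.contains(p.representative_point())),
                key=lambda i: shells[i].area, default=None)
            if parent is not None:
                holes.append((parent, p))
    out = []
    for i, s in enumerate(shells):
        hh = [h.exterior.coords for j, h in holes if j == i]
        out.append(Polygon(s.exterior.coords, hh))
    merged = unary_union(out)
    if merged.geom_type == "Polygon":
        merged = MultiPolygon([merged])
    return merged


def fit_kde_home_range(locations: pd.DataFrame, isopleth: float = 0.95,
                       grid_size: int = 200) -> HomeRange:
    """Bivariate-normal KDE home range at the given isopleth.

    The reference bandwidth is ``href = sigma * n^(-1/6)`` with
    ``sigma = sqrt((var_x + var_y) / 2)``; the density is evaluated on a
    ``grid_size`` x ``grid_size`` lattice padded 3*href beyond the data,
    and the isopleth polygon is the smallest superlevel set holding the
    stated probability mass.
    """
    x = locations["x"].to_numpy(dtype=float)
    y = locations["y"].to_numpy(dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"insufficient data for a KDE home range (n={n})")
    sigma = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    if sigma == 0:
        raise ValueError("all locations identical: zero variance")
    h = sigma * n ** (-1.0 / 6.0)

    pad = 3.0 * h
    gx = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    gy = np.linspace(y.min() - pad, y.max() + pad, grid_size)
    # separable kernel: density = Ky^T Kx summed over points (matmul)
    kx = np.exp(-0.5 * ((gx[None, :] - x[:, None]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[None, :] - y[:, None]) / h) ** 2)
    dens = ky.T @ kx  # rows = y, cols = x
    dens /= dens.sum()

    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat)
    level = flat[np.searchsorted(cum, isopleth)]

    rings = []
    for contour in measure.find_contours(dens, level):
        if not np.allclose(contour[0], contour[-1]):
            contour = np.vstack([contour, contour[:1]])
        # contour coords are (row=y-index, col=x-index) in grid space
        rx = np.interp(contour[:, 1], np.arange(grid_size), gx)
        ry = np.interp(contour[:, 0], np.arange(grid_size), gy)
        rings.append(np.column_stack([rx, ry]))
    poly = _rings_to_multipolygon(rings)
    animal = (str(locations["animal_id"].iloc[0])
              if "animal_id" in locations else "")
    return HomeRange(animal_id=animal, isopleth=isopleth, polygon=poly,
                     area_km2=poly.area / 1e6, h_ref=h)


# ---------------------------------------------------------------------------
# availability sampling

def sample_available(home_range: HomeRange | MultiPolygon | Polygon,
                     n_used: int, ratio: int = 5,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Exactly ``ratio * n_used`` points uniform over the home-range polygon.

    Rejection sampling from the bounding box; deterministic under seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if n_used < 1:
        raise ValueError("need at least one used location")
    poly = home_range.polygon if isinstance(home_range, HomeRange) else home_range
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    xmin, ymin, xmax, ymax = poly.bounds
    target = ratio * n_used
    xs, ys = [], []
    got = 0
    frac = max(poly.area / ((xmax - xmin) * (ymax - ymin)), 1e-6)
    while got < target:
        m = int((target - got) / frac * 1.2) + 16
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        ok = contains_xy(poly, cx, cy)
        xs.append(cx[ok])
        ys.append(cy[ok])
        got += int(ok.sum())
    x = np.concatenate(xs)[:target]
    y = np.concatenate(ys)[:target]
    return pd.DataFrame({"x": x, "y": y})


# ---------------------------------------------------------------------------
# used-available table

@dataclass
class UsedAvailableTable:
    """Response-labelled design table with frozen scaling metadata.

    ``df`` columns: response (1 used / 0 available), animal_id, pack_id,
    study_area, raw_<name> columns, scaled continuous columns (bare
    names), and cover_<label> indicator columns.  ``scaling`` maps each
    continuous covariate to its (mean, sd) on the fitting table; those
    frozen values are reused when predicting to new landscapes.
    """

    df: pd.DataFrame
    scaling: dict[str, tuple[float, float]]
    reference_level: str
    cover_levels: list[str] = field(default_factory=list)
    n_dropped_missing: int = 0

    @property
    def n_used(self) -> int:
        return int((self.df["response"] == 1).sum())

    @property
    def n_available(self) -> int:
        return int((self.df["response"] == 0).sum())

    def scaling_to_json(self) -> dict:
        return {
            "scaling": {k: {"mean": m, "sd": s}
                        for k, (m, s) in self.scaling.items()},
            "reference_level": self.reference_level,
            "cover_levels": self.cover_levels,
        }


def extract_covariates(points: pd.DataFrame, landscape: LandscapeStack
                       ) -> pd.DataFrame:
    """Raw covariate values at each point's containing cell (NaN off-grid)."""
    g = landscape.grid
    rows, cols = g.cell_index(points["x"].to_numpy(), points["y"].to_numpy())
    out = {}
    ok = rows >= 0
    for name, layer in landscape.layers.items():
        vals = np.full(len(points), np.nan)
        vals[ok] = layer.values[rows[ok], cols[ok]]
        out[name] = vals
    return pd.DataFrame(out, index=points.index)


def assemble_table(used: pd.DataFrame, available: pd.DataFrame,
                   landscape: LandscapeStack,
                   reference_level: str = "conifer",
                   home_ranges: dict[str, HomeRange] | None = None,
                   ) -> UsedAvailableTable:
    """Build the used-available design table.

    ``used`` needs animal_id/pack_id/study_area/x/y; ``available`` needs
    x/y plus (optionally) the same id columns.  If ``home_ranges`` is
    given, used points outside their animal's home range are excluded
    (and counted).  Points whose cell has any missing covariate are
    dropped with a logged count.
    """
    used = used.copy()
    used["response"] = 1
    available = available.copy()
    available["response"] = 0
    for col in ("animal_id", "pack_id", "study_area"):
        if col not in available:
            available[col] = ""
        if col not in used:
            used[col] = ""

    n_outside = 0
    if home_ranges is not None:
        keep = np.ones(len(used), dtype=bool)
        for animal, hr in home_ranges.items():
            m = used["animal_id"] == animal
            inside = hr.contains(used.loc[m, "x"].to_numpy(),
                                 used.loc[m, "y"].to_numpy())
            keep[m.to_numpy()] &= inside
        n_outside = int((~keep).sum())
        if n_outside:
            logger.info("excluded %d used points outside home ranges",
                        n_outside)
        used = used.loc[keep]

    cols = ["response", "animal_id", "pack_id", "study_area", "x", "y"]
    pts = pd.concat([used[cols], available[cols]], ignore_index=True)
    cov = extract_covariates(pts, landscape)
    complete = cov.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d points on missing-covariate cells", n_dropped)
    pts = pts.loc[complete].reset_index(drop=True)
    cov = cov.loc[complete].reset_index(drop=True)

    df = pts.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for name in CONTINUOUS_LAYERS:
        if name not in cov:
            continue
        raw = cov[name].to_numpy()
        mean = float(raw.mean())
        sd = float(raw.std(ddof=1))
        if sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        df[f"raw_{name}"] = raw
        df[name] = (raw - mean) / sd
        scaling[name] = (mean, sd)

    cover_levels: list[str] = []
    if "cover" in cov:
        codes = cov["cover"].astype(int)
        labels = codes.map(landscape.cover_codebook)
        if reference_level not in set(labels):
            raise ValueError(
                f"reference level {reference_level!r} absent from the data")
        df["raw_cover"] = labels.to_numpy()
        for label in sorted(set(labels)):
            if label == reference_level:
                continue
            df[f"cover_{label}"] = (labels == label).astype(float).to_numpy()
            cover_levels.append(label)

    return UsedAvailableTable(df=df, scaling=scaling,
                              reference_level=reference_level,
                              cover_levels=cover_levels,
                              n_dropped_missing=n_dropped + n_outside)
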