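"""Topographic and anthropogenic covariate rasters derived from a DEM and roads.

Implements the standard indices used in third-order habitat-selection
analyses on a 30 m grid:

* slope (degrees) by Horn's 8-neighbour finite-difference method;
* TRI, the terrain ruggedness index: mean absolute elevation difference
  between a cell and its 8 neighbours;
* TPI, the topographic position index: focal elevation minus the mean
  elevation of a square window of roughly 1 km^2 centred on the cell
  (focal cell excluded from the mean);
* road density: km of road per km^2 in a moving square window.

Edge policy: a derived cell whose full neighbourhood/window is not on the
grid is missing (NaN); downstream stages drop missing cells.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .grids import Grid, RoadNetwork

__all__ = ["derive_slope", "derive_tri", "derive_tpi", "derive_road_density"]


def _check_min_shape(dem: Grid) -> None:
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("DEM must be at least 3x3 cells")


def _neighbor_views(z: np.ndarray):
    """The 8 shifted views of the interior of ``z`` (3x3 neighbourhood).

    Returned in compass order for a row-0-south array:
    nw, n, ne, w, e, sw, s, se relative to the interior block.
    """
    return {
        "sw": z[:-2, :-2], "s": z[:-2, 1:-1], "se": z[:-2, 2:],
        "w": z[1:-1, :-2],                    "e": z[1:-1, 2:],
        "nw": z[2:, :-2],  "n": z[2:, 1:-1],  "ne": z[2:, 2:],
    }


def derive_slope(dem: Grid) -> Grid:
    """Slope in degrees by Horn's method; border cells missing."""
    _check_min_shape(dem)
    z = dem.values
    nb = _neighbor_views(z)
    c = dem.cell_size
    # Horn 1981: third-order finite difference weighted by inverse distance
    dzdx = ((nb["ne"] + 2 * nb["e"] + nb["se"])
            - (nb["nw"] + 2 * nb["w"] + nb["sw"])) / (8 * c)
    dzdy = ((nb["nw"] + 2 * nb["n"] + nb["ne"])
            - (nb["sw"] + 2 * nb["s"] + nb["se"])) / (8 * c)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out = np.full_like(z, np.nan)
    out[1:-1, 1:-1] = slope
    return dem.copy_with(out)


def derive_tri(dem: Grid) -> Grid:
    """Terrain ruggedness: mean |dz| to the 8 neighbours; border missing."""
    _check_min_shape(dem)
    z = dem.values
    center = z[1:-1, 1:-1]
    diffs = [np.abs(center - v) for v in _neighbor_views(z).values()]
    tri = np.mean(diffs, axis=0)
    out = np.full_like(z, np.nan)
    out[1:-1, 1:-1] = tri
    return dem.copy_with(out)


def window_cells(window_m: float, cell_size: float) -> int:
    """Odd window side in cells closest to ``window_m`` metres."""
    k = int(round(window_m / cell_size))
    if k % 2 == 0:
        k += 1
    return max(k, 3)


def _window_mean(z: np.ndarray, k: int) -> np.ndarray:
    """Mean over a k x k window via an integral image.

    NaN where the window leaves the grid or contains a missing cell
    (full-neighbourhood edge policy).
    """
    n, m = z.shape
    r = k // 2
    missing = ~np.isfinite(z)
    zz = np.where(missing, 0.0, z)
    pad = np.zeros((n + 1, m + 1))
    pad[1:, 1:] = zz.cumsum(axis=0).cumsum(axis=1)
    wsum = pad[k:, k:] - pad[:-k, k:] - pad[k:, :-k] + pad[:-k, :-k]
    padm = np.zeros((n + 1, m + 1))
    padm[1:, 1:] = missing.astype(float).cumsum(axis=0).cumsum(axis=1)
    wmiss = padm[k:, k:] - padm[:-k, k:] - padm[k:, :-k] + padm[:-k, :-k]
    out = np.full((n, m), np.nan)
    interior = wsum / (k * k)
    interior[wmiss > 0] = np.nan
    out[r:n - r, r:m - r] = interior
    return out


def derive_tpi(dem: Grid, window_m: float = 1000.0) -> Grid:
    """Topographic position index over a ~``window_m`` square window.

    Positive on ridges and peaks, negative in drainages.  The focal cell
    is excluded from the window mean.
    """
    _check_min_shape(dem)
    if window_m < 3 * dem.cell_size:
        raise ValueError("window_m must be at least 3 cells wide")
    k = window_cells(window_m, dem.cell_size)
    if k > min(dem.n_rows, dem.n_cols):
        warnings.warn("TPI window larger than grid: all cells missing",
                      stacklevel=2)
        return dem.copy_with(np.full_like(dem.values, np.nan))
    z = dem.values
    mean_incl = _window_mean(z, k)
    n = k * k
    mean_excl = (mean_incl * n - z) / (n - 1)
    return dem.copy_with(z - mean_excl)


def _segment_lengths_per_cell(template: Grid, p0: np.ndarray, p1: np.ndarray,
                              acc: np.ndarray) -> None:
    """Accumulate the length of segment p0->p1 inside each grid cell.

    The segment is split at every crossing of a cell boundary, and each
    piece's length is credited to the cell containing its midpoint.
    """
    x0, y0 = template.origin
    c = template.cell_size
    seg = p1 - p0
    length = float(np.hypot(*seg))
    if length == 0:
        return
    ts = [0.0, 1.0]
    for axis, o in ((0, x0), (1, y0)):
        lo = min(p0[axis], p1[axis])
        hi = max(p0[axis], p1[axis])
        first = int(np.ceil((lo - o) / c))
        last = int(np.floor((hi - o) / c))
        for i in range(first, last + 1):
            boundary = o + i * c
            if seg[axis] != 0:
                t = (boundary - p0[axis]) / seg[axis]
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts = np.unique(ts)
    mids = p0 + np.outer((ts[:-1] + ts[1:]) / 2.0, seg)
    rows, cols = template.cell_index(mids[:, 0], mids[:, 1])
    piece_len = np.diff(ts) * length
    ok = rows >= 0
    np.add.at(acc, (rows[ok], cols[ok]), piece_len[ok])


def rasterize_road_length(roads: RoadNetwork, template: Grid) -> Grid:
    """Exact road length (m) per grid cell."""
    acc = np.zeros((template.n_rows, template.n_cols))
    for line in roads.polylines:
        coords = np.asarray(line.coords, dtype=float)
        for a, b in zip(coords[:-1], coords[1:]):
            _segment_lengths_per_cell(template, a, b, acc)
    return template.copy_with(acc)


def derive_road_density(roads: RoadNetwork, template: Grid,
                        window_m: float = 1000.0) -> Grid:
    """Road density (km/km^2): road length in a moving square window
    divided by the window area.  Paved and unpaved roads are pooled.

    The window side is rounded to an odd number of cells so it aligns
    exactly with cell boundaries, making the cell-wise length
    rasterization an exact geometric clip of the window.
    """
    k = window_cells(window_m, template.cell_size)
    length_m = rasterize_road_length(roads, template).values
    window_sum_m = _window_mean(length_m, k) * (k * k)
    side_km = k * template.cell_size / 1000.0
    density = (window_sum_m / 1000.0) / (side_km ** 2)
    # integral-image cancellation can leave values a few ulp below zero
    density = np.where(density < 0, 0.0, density)
    return template.copy_with(density)


def derive_all(dem: Grid, roads: RoadNetwork | None = None,
               tpi_window_m: float = 1000.0,
               road_window_m: float = 1000.0) -> dict[str, Grid]:
    """Slope, TPI, TRI (and road density if roads given) from one DEM."""
    out = {
        "elevation": dem,
        "slope": derive_slope(dem),
        "tpi": derive_tpi(dem, tpi_window_m),
        "tri": derive_tri(dem),
    }
    if roads is not None:
        out["road_density"] = derive_road_density(roads, dem, road_window_m)
    return out
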