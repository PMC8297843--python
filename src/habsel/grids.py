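"""Planar raster grids, co-registered landscape stacks, and road networks.

All spatial data live in one planar metric coordinate system (units:
metres).  A :class:`Grid` stores per-cell values as a 2-D float array with
``NaN`` marking missing cells; row 0 is the *southernmost* row, so the
array is stored "south up" relative to the usual image convention.  Cell
``(i, j)`` covers the half-open square
``[x0 + j*c, x0 + (j+1)*c) x [y0 + i*c, y0 + (i+1)*c)`` where ``(x0, y0)``
is the lower-left origin and ``c`` the cell size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, mapping, shape

__all__ = [
    "Grid",
    "LandscapeStack",
    "RoadNetwork",
    "read_ascii_grid",
    "write_ascii_grid",
    "CONTINUOUS_LAYERS",
    "LAYER_NAMES",
]

#: layer names a stack may carry, with units
LAYER_NAMES = (
    "elevation",      # m
    "slope",          # degrees
    "tpi",            # m
    "tri",            # m
    "canopy",         # percent, 0-100
    "road_density",   # km per km^2
    "cover",          # categorical code
)

#: layers treated as continuous model covariates
CONTINUOUS_LAYERS = ("slope", "tpi", "tri", "canopy", "road_density")


@dataclass
class Grid:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values
        2-D array, shape ``(n_rows, n_cols)``; ``NaN`` = missing.
        Row 0 is the southernmost row.
    cell_size
        Cell edge length in metres (> 0).
    origin
        ``(x, y)`` of the lower-left corner.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edge."""
        x0, y0 = self.origin
        return (x0, y0,
                x0 + self.n_cols * self.cell_size,
                y0 + self.n_rows * self.cell_size)

    def x_centers(self) -> np.ndarray:
        x0 = self.origin[0]
        return x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        y0 = self.origin[1]
        return y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points ``(x, y)``.

        Half-open cell intervals: a point exactly on a cell's east/north
        edge belongs to the next cell.  Points outside the grid get -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def value_at(self, x, y) -> np.ndarray:
        """Cell values at points; NaN outside the grid."""
        row, col = self.cell_index(x, y)
        out = np.full(np.shape(row), np.nan)
        ok = row >= 0
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def is_aligned(self, other: "Grid") -> bool:
        return (self.values.shape == other.values.shape
                and self.cell_size == other.cell_size
                and self.origin == other.origin)

    def copy_with(self, values: np.ndarray) -> "Grid":
        return Grid(values=np.asarray(values, dtype=float),
                    cell_size=self.cell_size, origin=self.origin)


DEFAULT_CODEBOOK = {
    0: "conifer",
    1: "grass_shrub",
    2: "burn",
    3: "logged",
    4: "riparian",
    5: "other",
}


@dataclass
class LandscapeStack:
    """Co-registered covariate rasters keyed by layer name."""

    layers: dict[str, Grid]
    cover_codebook: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CODEBOOK))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        grids = list(self.layers.values())
        if not grids:
            raise ValueError("empty landscape stack")
        ref = grids[0]
        for name, g in self.layers.items():
            if name not in LAYER_NAMES:
                raise ValueError(f"unknown layer name {name!r}")
            if not g.is_aligned(ref):
                raise ValueError(f"layer {name!r} is not co-registered")
        if "canopy" in self.layers:
            v = self.layers["canopy"].values
            if np.nanmin(v) < 0 or np.nanmax(v) > 100:
                raise ValueError("canopy must lie in [0, 100]")
        for name in ("road_density", "tri"):
            if name in self.layers and np.nanmin(self.layers[name].values) < 0:
                raise ValueError(f"{name} must be non-negative")
        if "cover" in self.layers:
            codes = self.layers["cover"].values
            present = np.unique(codes[np.isfinite(codes)]).astype(int)
            missing = [c for c in present if c not in self.cover_codebook]
            if missing:
                raise ValueError(f"cover codes {missing} absent from codebook")

    @property
    def grid(self) -> Grid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    # ------------------------------------------------------------------ I/O
    def write_dir(self, out_dir: str | Path) -> None:
        """Write one ASCII-grid file per layer plus the cover codebook."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, g in self.layers.items():
            write_ascii_grid(g, out_dir / f"{name}.asc")
        with open(out_dir / "cover_codebook.json", "w") as fh:
            json.dump({str(k): v for k, v in self.cover_codebook.items()}, fh,
                      indent=1)

    @classmethod
    def read_dir(cls, in_dir: str | Path) -> "LandscapeStack":
        in_dir = Path(in_dir)
        layers = {}
        for name in LAYER_NAMES:
            p = in_dir / f"{name}.asc"
            if p.exists():
                layers[name] = read_ascii_grid(p)
        cb_path = in_dir / "cover_codebook.json"
        if cb_path.exists():
            with open(cb_path) as fh:
                codebook = {int(k): v for k, v in json.load(fh).items()}
        else:
            codebook = dict(DEFAULT_CODEBOOK)
        return cls(layers=layers, cover_codebook=codebook)


@dataclass
class RoadNetwork:
    """Paved + unpaved road polylines in the landscape's coordinate system."""

    polylines: list[LineString]
    road_class: list[str] = field(default_factory=list)  # "paved"|"unpaved"

    def __post_init__(self) -> None:
        if not self.road_class:
            self.road_class = ["unpaved"] * len(self.polylines)
        if len(self.road_class) != len(self.polylines):
            raise ValueError("one road class per polyline required")
        for line in self.polylines:
            coords = np.asarray(line.coords)
            if len(coords) < 2:
                raise ValueError("polyline needs at least 2 vertices")
            if not np.all(np.isfinite(coords)):
                raise ValueError("polyline has non-finite coordinates")

    def total_length_km(self) -> float:
        return sum(l.length for l in self.polylines) / 1000.0

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {"type": "Feature",
             "geometry": mapping(line),
             "properties": {"class": cls}}
            for line, cls in zip(self.polylines, self.road_class)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RoadNetwork":
        with open(path) as fh:
            gj = json.load(fh)
        lines: list[LineString] = []
        classes: list[str] = []
        for feat in gj.get("features", []):
            geom = shape(feat["geometry"])
            road_class = feat.get("properties", {}).get("class", "unpaved")
            if geom.geom_type == "LineString":
                parts = [geom]
            elif geom.geom_type == "MultiLineString":
                parts = list(geom.geoms)
            else:
                raise ValueError(f"unsupported geometry {geom.geom_type}")
            for part in parts:
                lines.append(part)
                classes.append(road_class)
        return cls(polylines=lines, road_class=classes)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O.  Plain-text georeferenced raster format: a 6-line
# header followed by rows of cell values, written north-to-south.

def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = -9999.0) -> None:
    vals = np.flipud(grid.values)  # file rows run north -> south
    vals = np.where(np.isfinite(vals), vals, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Grid:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)
    nodata = meta.get("nodata_value", -9999.0)
    body = np.where(body == nodata, np.nan, body)
    return Grid(values=np.flipud(body),
                cell_size=meta["cellsize"],
                origin=(meta["xllcorner"], meta["yllcorner"]))
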