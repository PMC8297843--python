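"""Binned cross-validation of RSF surfaces (Boyce-style).

Internal validation: the fitted model's predictions over the study-area
landscape are cut into 10 equal-interval bins; for each of 5 folds of the
used locations, the per-bin *area-adjusted* frequency of use (used count
divided by the number of landscape cells in the bin) is correlated with
bin rank by Spearman's r_s, and the mean r_s over folds is reported.

External validation: predictions over the test landscape are cut into 10
*equal-area* deciles (each holding 10% of cells); out-of-sample used
locations are assigned to deciles by their cell's predicted value and r_s
is computed between decile rank and raw frequency of use.

A predictive surface yields r_s near +1; a surface whose ranking is
inverted relative to actual use yields r_s near -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import LandscapeStack
from .preprocess import UsedAvailableTable
from .rsf import RSFModel, predict_rsf

__all__ = [
    "ValidationResult",
    "kfold_split",
    "internal_validate",
    "external_validate",
    "spearman",
]


@dataclass
class ValidationResult:
    mode: str                       # "internal" | "external"
    bin_ranks: np.ndarray           # 1..n_bins
    used_counts: list[np.ndarray]   # one vector per fold (single for external)
    bin_areas: np.ndarray           # cell count per bin
    frequencies: list[np.ndarray]   # area-adjusted (internal) or raw (external)
    rs_per_fold: list[float]
    mean_rs: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, (counts, freq) in enumerate(zip(self.used_counts,
                                               self.frequencies)):
            for r, c, a, q in zip(self.bin_ranks, counts, self.bin_areas,
                                  freq):
                rows.append({"fold": f + 1, "bin_rank": int(r),
                             "used_count": int(c), "bin_area_cells": int(a),
                             "frequency": q})
        return pd.DataFrame(rows)


def spearman(x, y) -> tuple[float, bool]:
    """Spearman rank correlation with a degenerate-input convention.

    Returns ``(r_s, degenerate)``; a constant vector gives ``(0.0, True)``
    rather than an error so validation pipelines keep running.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, True
    r = float(stats.spearmanr(x, y).statistic)
    return r, False


def kfold_split(n_used: int, k: int = 5,
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random fold labels 0..k-1 for used locations; sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_used < k:
        raise ValueError("fewer used locations than folds")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    labels = np.arange(n_used) % k
    rng.shuffle(labels)
    return labels


def _surface_values(model: RSFModel, landscape: LandscapeStack
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted surface grid values and the finite-cell vector."""
    surface = predict_rsf(model, landscape)
    vals = surface.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("prediction surface is entirely missing")
    return vals, finite


def _predict_at_points(model: RSFModel, landscape: LandscapeStack,
                       x: np.ndarray, y: np.ndarray) -> np.ndarray:
    surface = predict_rsf(model, landscape)
    return landscape.grid.copy_with(surface.values).value_at(x, y)


def internal_validate(model: RSFModel, table: UsedAvailableTable,
                      landscape: LandscapeStack, k: int = 5,
                      n_bins: int = 10,
                      seed: int | np.random.Generator = 0) -> ValidationResult:
    """k-fold equal-interval validation with area-adjusted frequencies.

    The model is the one fitted to the full table; folds partition the
    used locations only.  Bin edges are equal intervals spanning the
    predicted surface over the landscape; zero-area bins are excluded
    from the correlation.
    """
    vals, finite = _surface_values(model, landscape)
    lo, hi = float(finite.min()), float(finite.max())
    if hi - lo <= 0:
        raise ValueError("degenerate (constant) prediction surface")
    edges = np.linspace(lo, hi, n_bins + 1)
    area = np.histogram(finite, bins=edges)[0]

    used = table.df[table.df["response"] == 1]
    pred_used = landscape.grid.copy_with(vals).value_at(
        used["x"].to_numpy(), used["y"].to_numpy())
    ok = np.isfinite(pred_used)
    pred_used = pred_used[ok]
    folds = kfold_split(len(pred_used), k, seed)

    ranks = np.arange(1, n_bins + 1)
    used_counts, freqs, rs_list = [], [], []
    degenerate = False
    for f in range(k):
        pv = pred_used[folds == f]
        idx = np.clip(np.searchsorted(edges, pv, side="right") - 1,
                      0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        nonzero = area > 0
        freq = np.full(n_bins, np.nan)
        freq[nonzero] = counts[nonzero] / area[nonzero]
        r, dgn = spearman(ranks[nonzero], freq[nonzero])
        degenerate |= dgn
        used_counts.append(counts)
        freqs.append(freq)
        rs_list.append(r)
    return ValidationResult(mode="internal", bin_ranks=ranks,
                            used_counts=used_counts, bin_areas=area,
                            frequencies=freqs, rs_per_fold=rs_list,
                            mean_rs=float(np.mean(rs_list)),
                            degenerate=degenerate)


def external_validate(model: RSFModel, used: pd.DataFrame,
                      landscape: LandscapeStack,
                      n_bins: int = 10) -> ValidationResult:
    """Equal-area decile validation on out-of-sample used locations.

    Deciles are ranked cell groups of the predicted surface over the test
    landscape, each holding 1/n_bins of the cells (ties broken by cell
    order after a stable sort); frozen scaling from the fitting table is
    reused through the model's metadata.
    """
    vals, finite = _surface_values(model, landscape)
    mode_share = (pd.Series(finite).value_counts().iloc[0]) / finite.size
    if mode_share > 0.5:
        raise ValueError("over half of the cells share one predicted value: "
                         "equal-area deciles undefined")

    flat = vals.ravel()
    finite_idx = np.nonzero(np.isfinite(flat))[0]
    order = finite_idx[np.argsort(flat[finite_idx], kind="stable")]
    decile_flat = np.full(flat.size, -1)
    decile_flat[order] = (np.arange(order.size) * n_bins) // order.size
    decile_grid = decile_flat.reshape(vals.shape)

    g = landscape.grid
    rows, cols = g.cell_index(used["x"].to_numpy(), used["y"].to_numpy())
    ok = rows >= 0
    dec = decile_grid[rows[ok], cols[ok]]
    dec = dec[dec >= 0]

    counts = np.bincount(dec, minlength=n_bins)
    area = np.bincount(decile_flat[decile_flat >= 0], minlength=n_bins)
    ranks = np.arange(1, n_bins + 1)
    r, degenerate = spearman(ranks, counts)
    return ValidationResult(mode="external", bin_ranks=ranks,
                            used_counts=[counts], bin_areas=area,
                            frequencies=[counts.astype(float)],
                            rs_per_fold=[r], mean_rs=r,
                            degenerate=degenerate)


def plot_validation(result: ValidationResult, path) -> None:
    """Frequency-vs-bin-rank panel (one line per fold)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for f, freq in enumerate(result.frequencies):
        ax.plot(result.bin_ranks, freq, marker="o",
                label=f"fold {f + 1}" if result.mode == "internal" else None)
    ylab = ("area-adjusted frequency of use" if result.mode == "internal"
            else "frequency of use")
    ax.set_xlabel("RSF bin rank")
    ax.set_ylabel(ylab)
    ax.set_title(f"{result.mode} validation, mean $r_s$ = {result.mean_rs:.3f}")
    if result.mode == "internal":
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
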