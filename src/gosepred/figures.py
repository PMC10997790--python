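"""Figure rendering for prediction sets.

Figures are artifacts, never assertions: tests check the numeric tables
underneath, not pixels. All plots use the Agg backend and are written as
PNG (or any extension matplotlib understands).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from gosepred.cohort import GOSE_LEVELS
from gosepred.metrics import (
    calibration_curve,
    category_proportion_discrepancy,
    confusion_matrix,
    error_distribution,
)
from gosepred.predictors import PredictionSet

__all__ = ["render_figures"]


def _confusion_heatmap(pset: PredictionSet, path: Path) -> None:
    mat = confusion_matrix(pset.predicted, pset.observed)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(mat, cmap="viridis", origin="upper")
    ax.set_xticks(range(8), [str(g) for g in GOSE_LEVELS])
    ax.set_yticks(range(8), [str(g) for g in GOSE_LEVELS])
    ax.set_xlabel("Predicted GOSE")
    ax.set_ylabel("Observed GOSE")
    for i in range(8):
        for j in range(8):
            if mat[i, j]:
                ax.text(j, i, str(mat[i, j]), ha="center", va="center", fontsize=7, color="w")
    fig.colorbar(im, ax=ax, label="count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _proportion_bars(pset: PredictionSet, path: Path) -> None:
    pcp, ocp, tcpd, mcpd = category_proportion_discrepancy(pset.predicted, pset.observed)
    x = np.arange(8)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(x - 0.2, ocp, width=0.4, label="observed", color="#4c72b0")
    ax.bar(x + 0.2, pcp, width=0.4, label="predicted", color="#dd8452")
    ax.set_xticks(x, [str(g) for g in GOSE_LEVELS])
    ax.set_xlabel("GOSE category")
    ax.set_ylabel("proportion")
    ax.set_title(f"TCPD={tcpd:.2f}  MCPD={mcpd:.2f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _error_histogram(pset: PredictionSet, path: Path) -> None:
    hist = error_distribution(pset.predicted, pset.observed)
    deltas = sorted(hist)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(deltas, [hist[d] for d in deltas], color="#55a868")
    ax.set_xlabel("observed GOSE - predicted GOSE")
    ax.set_ylabel("count")
    ax.axvline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _calibration_panels(pset: PredictionSet, path: Path, n_bins: int) -> int:
    """Per-category reliability plots; categories with zero predicted mass
    everywhere are skipped. Returns the number of panels drawn."""
    active = [
        c for c in GOSE_LEVELS if float(pset.probabilities[:, c - 1].max(initial=0)) > 0
    ]
    if not active:
        return 0
    ncols = min(4, len(active))
    nrows = int(np.ceil(len(active) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 3.0 * nrows), squeeze=False)
    import warnings

    for ax, cat in zip(axes.ravel(), active):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curve = calibration_curve(pset.probabilities, pset.observed, cat, n_bins=n_bins)
        xs = [b[0] for b in curve.bins]
        ys = [b[1] for b in curve.bins]
        ses = [b[2] for b in curve.bins]
        ax.fill_between(
            xs,
            [y - 2 * s for y, s in zip(ys, ses)],
            [y + 2 * s for y, s in zip(ys, ses)],
            color="0.8",
            label="±2 SE",
        )
        ax.plot(xs, ys, "-", color="k", lw=1.5)
        lim = max([*xs, *ys, 0.05])
        ax.plot([0, lim], [0, lim], "--", color="0.4", lw=0.8)
        ax.set_title(f"GOSE {cat}", fontsize=9)
        ax.set_xlabel("predicted probability", fontsize=8)
        ax.set_ylabel("observed frequency", fontsize=8)
    for ax in axes.ravel()[len(active) :]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return len(active)


def render_figures(
    pset: PredictionSet, outdir, prefix: str = "", n_bins: int = 10
) -> dict[str, Path]:
    """Write the four figure types for a prediction set.

    Returns a mapping of figure kind to written path: confusion heat map
    (rows observed), paired predicted/observed proportion bars, the error
    histogram over -7..+7, and per-category calibration panels with 2-SE
    bands.
    """
    if len(pset) == 0:
        raise ValueError("cannot render figures for an empty prediction set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{prefix}_" if prefix else ""
    paths = {
        "confusion": outdir / f"{tag}confusion.png",
        "proportions": outdir / f"{tag}category_proportions.png",
        "errors": outdir / f"{tag}error_distribution.png",
        "calibration": outdir / f"{tag}calibration.png",
    }
    _confusion_heatmap(pset, paths["confusion"])
    _proportion_bars(pset, paths["proportions"])
    _error_histogram(pset, paths["errors"])
    n_panels = _calibration_panels(pset, paths["calibration"], n_bins)
    if n_panels == 0:
        paths.pop("calibration")
    return paths
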