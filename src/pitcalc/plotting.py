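"""Visual QC exports: population raster, proportion heatmap, PCA scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def raster(dff: np.ndarray, frame_interval_s: float, path, vmax: float = 1.0) -> None:
    """Cells × time heatmap of ΔF/Fmin; one row per cell."""
    fig, ax = plt.subplots(figsize=(8, 4))
    extent = (0, dff.shape[1] * frame_interval_s, dff.shape[0], 0)
    im = ax.imshow(dff, aspect="auto", extent=extent, vmin=0, vmax=vmax, cmap="viridis")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    fig.colorbar(im, label="ΔF/Fmin")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def proportion_heatmap(table: pd.DataFrame, path) -> None:
    """Tumor × category/stimulus percentage heatmap."""
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(table) + 1.5))
    im = ax.imshow(table.to_numpy(dtype=float), aspect="auto", cmap="magma", vmin=0, vmax=100)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.shape[0]), table.index)
    fig.colorbar(im, label="% of viable cells")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def pca_scatter(scores: pd.DataFrame, explained_pct, path, recurrent: dict | None = None) -> None:
    """PC1 vs PC2 scatter, colored by recurrence when provided."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for tumor, row in scores.iterrows():
        rec = (recurrent or {}).get(tumor)
        color = "tab:green" if rec else ("tab:blue" if rec is not None else "gray")
        ax.scatter(row["PC1"], row["PC2"], color=color)
        ax.annotate(str(tumor), (row["PC1"], row["PC2"]), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel(f"PC1 ({explained_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({explained_pct[1]:.1f}%)")
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
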