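"""Optional plots: FST heatmap, MDS scatter, PCA biplot.

matplotlib is imported lazily so the core pipeline has no hard
dependency on it; install the ``plot`` extra to use this module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .differentiation import FstMatrix
from .haplogroups import PcaResult


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def fst_heatmap(fst: FstMatrix, path: str | Path, cmap: str = "viridis"):
    """Heatmap of a pairwise PhiST matrix."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(fst.values, cmap=cmap)
    ax.set_xticks(range(len(fst.groups)), fst.groups, rotation=90, fontsize=7)
    ax.set_yticks(range(len(fst.groups)), fst.groups, fontsize=7)
    fig.colorbar(im, ax=ax, label=r"$\Phi_{ST}$")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def mds_scatter(coords, path: str | Path):
    """Scatter of classical-MDS coordinates (first two axes)."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 5))
    xs = coords.iloc[:, 0]
    ys = coords.iloc[:, 1] if coords.shape[1] > 1 else np.zeros(len(coords))
    ax.scatter(xs, ys)
    for label, x, y in zip(coords.index, xs, ys):
        ax.annotate(str(label), (x, y), fontsize=7)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1] if coords.shape[1] > 1 else "")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pca_biplot(res: PcaResult, path: str | Path, scale_arrows: float = 1.0):
    """Group scores with haplogroup loading arrows on PC1/PC2."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 5))
    xs = res.scores.iloc[:, 0]
    ys = (
        res.scores.iloc[:, 1]
        if res.scores.shape[1] > 1
        else np.zeros(len(res.scores))
    )
    ax.scatter(xs, ys)
    for label, x, y in zip(res.scores.index, xs, ys):
        ax.annotate(str(label), (x, y), fontsize=7)
    span = max(float(np.abs(xs).max()), float(np.abs(ys).max()), 1e-9)
    arrows = res.loadings.iloc[:, : min(2, res.loadings.shape[1])]
    for hap, row in arrows.iterrows():
        dx = row.iloc[0] * span * scale_arrows
        dy = (row.iloc[1] if len(row) > 1 else 0.0) * span * scale_arrows
        ax.annotate(
            "", xy=(dx, dy), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="firebrick", lw=0.8),
        )
        ax.annotate(str(hap), (dx, dy), color="firebrick", fontsize=7)
    evr = res.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
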