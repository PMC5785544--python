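"""Figures: phylomorphospace, regression-score allometry, deformation grids."""

from __future__ import annotations

import numpy as np

from .trees import Phylogeny


def _axes(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(6, 5))
    return ax


def plot_phylomorphospace(tree: Phylogeny, tip_scores, ancestor_scores,
                          labels=None, ax=None, path=None):
    """Tips, reconstructed ancestors and connecting branches in PC1-PC2.

    ``ancestor_scores`` are internal-node scores ordered as
    ``tree.n_tips .. n_nodes-1``; branches are drawn between each node and
    its parent.
    """
    ax = _axes(ax)
    tip_scores = np.asarray(tip_scores)[:, :2]
    anc = np.asarray(ancestor_scores)[:, :2]
    allsc = np.vstack([tip_scores, anc])
    for nd in range(tree.n_nodes):
        par = tree.parent[nd]
        if par >= 0:
            ax.plot(allsc[[nd, par], 0], allsc[[nd, par], 1],
                    color="0.7", lw=0.6, zorder=1)
    if labels is not None:
        cats = sorted(set(labels))
        for c in cats:
            sel = np.asarray([l == c for l in labels])
            ax.scatter(tip_scores[sel, 0], tip_scores[sel, 1], s=14, label=c,
                       zorder=2)
        ax.legend(fontsize=7)
    else:
        ax.scatter(tip_scores[:, 0], tip_scores[:, 1], s=14, zorder=2)
    ax.scatter(anc[:, 0], anc[:, 1], s=8, color="k", marker=".", zorder=3)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("Phylomorphospace")
    if path:
        ax.figure.savefig(path, dpi=120)
    return ax


def plot_regression_score(scores, log_sizes, groups=None, ax=None, path=None):
    """Regression score vs log centroid size, by group (allometry figure)."""
    ax = _axes(ax)
    scores = np.asarray(scores)
    log_sizes = np.asarray(log_sizes)
    if groups is None:
        ax.scatter(log_sizes, scores, s=14)
    else:
        for g in sorted(set(groups)):
            sel = np.asarray([x == g for x in groups])
            ax.scatter(log_sizes[sel], scores[sel], s=14, label=g)
        ax.legend(fontsize=7)
    ax.set_xlabel("log centroid size")
    ax.set_ylabel("regression score")
    if path:
        ax.figure.savefig(path, dpi=120)
    return ax


def plot_deformation_grid(spline, n=20, ax=None, path=None):
    """Warped-grid visualization of a fitted 2D thin-plate spline."""
    from .tps import deformation_grid

    ax = _axes(ax)
    grid, warped = deformation_grid(spline, n=n)
    w = warped.reshape(n, n, 2)
    for i in range(n):
        ax.plot(w[i, :, 0], w[i, :, 1], color="0.6", lw=0.5)
        ax.plot(w[:, i, 0], w[:, i, 1], color="0.6", lw=0.5)
    ax.scatter(spline.target[:, 0], spline.target[:, 1], s=12, color="k")
    ax.set_aspect("equal")
    if path:
        ax.figure.savefig(path, dpi=120)
    return ax
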