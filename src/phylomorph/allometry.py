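"""Multivariate allometry: regression of shape on log centroid size.

The model regresses tangent-space shape on log centroid size, either as an
ordinary multivariate regression across species or — when a phylogeny is
supplied — through the origin on phylogenetically independent contrasts, the
form appropriate when species values are not independent.  Significance
comes from a permutation test against total independence of size and shape
(sizes shuffled across tips); the explained fraction is the predicted sum of
squares over the total.  Residual shapes (species space) support
allometry-corrected reanalysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .comparative import pic_matrix
from .trees import Phylogeny

log = logging.getLogger(__name__)

__all__ = ["AllometryModel", "AllometryResults", "regression_score"]


def regression_score(shapes: np.ndarray, slope_vector: np.ndarray) -> np.ndarray:
    """Project centred shapes onto the unit-normalized allometric slope.

    The standard univariate summary of a multivariate shape-on-size
    regression (the 'regression score' plotted against log size).
    """
    b = np.asarray(slope_vector, dtype=float).ravel()
    norm = np.linalg.norm(b)
    if norm == 0:
        raise ValueError("zero slope vector")
    X = np.atleast_2d(np.asarray(shapes, dtype=float))
    return (X - X.mean(axis=0)) @ (b / norm)


@dataclass
class AllometryResults:
    """Fitted allometric regression.

    ``percent_explained`` = 100 * predicted SS / total SS, computed in the
    space the slope was estimated in (contrasts when a tree was used);
    ``residual_shapes`` are species-space shapes with the size effect
    removed (centred).
    """

    slope_vector: np.ndarray
    percent_explained: float
    p_value: float
    residual_shapes: np.ndarray
    n_perm: int
    used_contrasts: bool
    percent_explained_species: float = np.nan
    model: "AllometryModel" = field(default=None, repr=False)

    def summary(self) -> str:
        basis = "independent contrasts" if self.used_contrasts else "species"
        lines = [
            "Multivariate regression of shape on log centroid size",
            f"  basis              : {basis}",
            f"  percent explained  : {self.percent_explained:.3f} %",
        ]
        if self.used_contrasts:
            lines.append(
                f"  (species-space fit : {self.percent_explained_species:.3f} %)")
        lines.append(
            f"  permutation p      : {self.p_value:.4g}  ({self.n_perm} perms)")
        return "\n".join(lines) + "\n"


class AllometryModel:
    """Shape-on-log-size regression, optionally phylogeny-corrected.

    Parameters
    ----------
    shapes : (n, p) array
        Tangent-space shape coordinates (rows = species/specimens).
    log_size : (n,) array
        Log centroid sizes.
    tree : Phylogeny, optional
        When given, the slope is estimated by regression through the origin
        of shape contrasts on size contrasts; rows must then follow
        ``names`` (or tip order).
    names : sequence of str, optional
        Row labels matching tree tips.
    """

    def __init__(self, shapes, log_size, tree: Phylogeny | None = None,
                 names=None):
        self.shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
        self.log_size = np.asarray(log_size, dtype=float).ravel()
        if self.shapes.shape[0] != self.log_size.size:
            raise ValueError("shapes and log_size disagree in length")
        if np.ptp(self.log_size) == 0:
            raise ValueError("log_size is constant; allometry undefined")
        self.tree = tree
        if tree is not None:
            if names is not None:
                order = [list(names).index(lab) for lab in tree.tip_labels]
                self.shapes = self.shapes[order]
                self.log_size = self.log_size[order]
            elif self.shapes.shape[0] != tree.n_tips:
                raise ValueError("rows do not match tree tips")

    @staticmethod
    def _fit_stats(Y, s, through_origin: bool):
        """Slope vector, predicted SS and total SS of Y ~ s."""
        if not through_origin:
            Y = Y - Y.mean(axis=0)
            s = s - s.mean()
        ss_s = float(s @ s)
        slope = (Y.T @ s) / ss_s
        pred_ss = float(slope @ slope) * ss_s
        tot_ss = float((Y ** 2).sum())
        return slope, pred_ss, tot_ss

    def fit(self, n_perm: int = 10000, seed=None) -> AllometryResults:
        if n_perm < 10:
            raise ValueError("n_perm must be at least 10")
        rng = np.random.default_rng(seed)
        Y, s = self.shapes, self.log_size
        n = Y.shape[0]

        if self.tree is not None:
            A = pic_matrix(self.tree)          # contrasts are linear in tips
            Uy = A @ Y
            slope, pred, tot = self._fit_stats(Uy, A @ s, through_origin=True)
            pct = 100.0 * pred / tot
            _, pred_sp, tot_sp = self._fit_stats(Y, s, through_origin=False)
            pct_species = 100.0 * pred_sp / tot_sp
            # Permute the size *contrasts* across nodes: under the null of
            # total size/shape independence with Brownian size evolution the
            # standardized contrasts are the iid, hence exchangeable, unit
            # (shuffling raw tip values instead destroys the phylogenetic
            # structure of size and badly inflates the null).
            us0 = A @ s
            count = 0
            for _ in range(n_perm):
                us = us0[rng.permutation(n - 1)]
                ss = float(us @ us)
                proj = Uy.T @ us
                perm_pred = float(proj @ proj) / ss
                if perm_pred >= pred:
                    count += 1
            used_contrasts = True
        else:
            slope, pred, tot = self._fit_stats(Y, s, through_origin=False)
            pct = 100.0 * pred / tot
            pct_species = pct
            Yc = Y - Y.mean(axis=0)
            count = 0
            for _ in range(n_perm):
                sp = s[rng.permutation(n)]
                spc = sp - sp.mean()
                ssp = float(spc @ spc)
                proj = Yc.T @ spc
                perm_pred = float(proj @ proj) / ssp
                if perm_pred >= pred:
                    count += 1
            used_contrasts = False

        p = (count + 1) / (n_perm + 1)
        sc = s - s.mean()
        residual = (Y - Y.mean(axis=0)) - np.outer(sc, slope)
        log.info("allometry: %s basis, %.3f%% explained, p=%.4g",
                 "contrast" if used_contrasts else "species", pct, p)
        return AllometryResults(slope_vector=slope, percent_explained=pct,
                                p_value=p, residual_shapes=residual,
                                n_perm=n_perm, used_contrasts=used_contrasts,
                                percent_explained_species=pct_species,
                                model=self)
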