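"""PCA morphospace over tangent-space shape coordinates."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["Morphospace", "pca"]


@dataclass
class Morphospace:
    """Principal-component morphospace.

    ``eigenvectors`` (p x m, orthonormal columns) span the retained axes;
    ``scores`` are the centred data projected onto them; ``variance_fraction``
    gives each axis' share of total tangent variance (non-increasing).
    """

    eigenvectors: np.ndarray       # (p, m)
    eigenvalues: np.ndarray        # (m,)
    scores: np.ndarray             # (n, m)
    variance_fraction: np.ndarray  # (m,)
    mean: np.ndarray               # (p,)
    mean_shape: np.ndarray = field(default=None)   # (k, d) when known

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]

    def project(self, data: np.ndarray) -> np.ndarray:
        """Scores of new points (e.g. reconstructed ancestors) in this space."""
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != self.eigenvectors.shape[0]:
            raise ValueError("data dimension does not match the morphospace")
        return (X - self.mean) @ self.eigenvectors

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Back-map scores to tangent coordinates (mean + scores @ V')."""
        S = np.atleast_2d(np.asarray(scores, dtype=float))
        return self.mean + S @ self.eigenvectors.T

    def axes_for_variance(self, fraction: float) -> int:
        """Smallest number of leading axes whose cumulative variance share
        exceeds ``fraction``."""
        cum = np.cumsum(self.variance_fraction)
        return int(np.searchsorted(cum, fraction) + 1)


def pca(tangent: np.ndarray, shape_kd=None) -> Morphospace:
    """Eigendecomposition of the specimen covariance of tangent coordinates.

    Axis signs are fixed deterministically: each eigenvector is oriented so
    its largest-magnitude loading is positive (axis polarity carries no
    meaning).  Axes with numerically zero variance are dropped.
    """
    X = np.asarray(tangent, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("PCA needs an (n >= 3) x p matrix")
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("zero total variance; morphospace undefined")
    keep = eigvals > max(1e-12 * eigvals[0], 0)
    eigvals = eigvals[keep]
    V = Vt[keep].T
    # deterministic sign convention
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = Xc @ V
    ms = Morphospace(eigenvectors=V, eigenvalues=eigvals, scores=scores,
                     variance_fraction=eigvals / total, mean=mean)
    if shape_kd is not None:
        ms.mean_shape = mean.reshape(shape_kd)
    log.info("pca: n=%d p=%d retained=%d PC1+PC2=%.1f%%", n, X.shape[1],
             len(eigvals), 100 * ms.variance_fraction[:2].sum())
    return ms
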