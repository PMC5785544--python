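"""Thin-plate spline interpolation between landmark configurations.

A TPS mapping carries a source configuration exactly onto a target while
minimizing the integral bending energy of the interpolant.  It decomposes
into an affine part plus a weighted sum of radial kernels centred at the
source landmarks: U(r) = r^2 log r^2 in 2D and U(r) = -r in 3D (the sign
that keeps the constrained kernel system positive semidefinite, so bending
energy is >= 0 and vanishes exactly when the target is an affine image of
the source).  Used to visualize shape change and to warp the species
nearest a reconstructed ancestor toward the ancestral landmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["ThinPlateSpline", "tps_fit", "warp_to_node", "deformation_grid"]


def _kernel(r: np.ndarray, d: int) -> np.ndarray:
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(r * r), 0.0)
        return out
    return -r


@dataclass
class ThinPlateSpline:
    """Fitted TPS mapping from ``source`` landmarks to ``target`` landmarks."""

    source: np.ndarray                 # (k, d)
    target: np.ndarray                 # (k, d)
    warp_coefficients: np.ndarray      # (k, d)
    affine: np.ndarray                 # (d+1, d)  rows: intercept then linear
    bending_energy: float
    _K: np.ndarray = field(default=None, repr=False)

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map probe points through the fitted spline (landmarks map exactly)."""
        P = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.source.shape[1]
        if P.shape[1] != d:
            raise ValueError("probe dimensionality mismatch")
        r = np.linalg.norm(P[:, None, :] - self.source[None, :, :], axis=2)
        return (_kernel(r, d) @ self.warp_coefficients
                + np.hstack([np.ones((len(P), 1)), P]) @ self.affine)


def tps_fit(source: np.ndarray, target: np.ndarray) -> ThinPlateSpline:
    """Fit the exact-interpolation thin-plate spline source -> target.

    Requires at least d+1 source landmarks in general position; a collinear
    (2D) or coplanar (3D) source set makes the system singular and raises.
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.shape != T.shape or S.ndim != 2:
        raise ValueError("source and target must be matching k x d arrays")
    k, d = S.shape
    if d not in (2, 3):
        raise ValueError("TPS implemented for d in {2, 3}")
    if k < d + 1:
        raise ValueError(f"need at least {d + 1} landmarks for d={d}")
    r = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=2)
    K = _kernel(r, d)
    P = np.hstack([np.ones((k, 1)), S])
    A = np.zeros((k + d + 1, k + d + 1))
    A[:k, :k] = K
    A[:k, k:] = P
    A[k:, :k] = P.T
    rhs = np.zeros((k + d + 1, d))
    rhs[:k] = T
    # rank check on the polynomial part catches degenerate landmark sets
    if np.linalg.matrix_rank(P, tol=1e-10 * max(1.0, np.abs(S).max())) < d + 1:
        raise ValueError("degenerate (collinear/coplanar) source landmarks")
    sol = np.linalg.solve(A, rhs)
    W = sol[:k]
    affine = sol[k:]
    energy = float(np.trace(W.T @ K @ W))
    energy = max(energy, 0.0)  # clip numerical noise; the form is PSD
    return ThinPlateSpline(source=S, target=T, warp_coefficients=W,
                           affine=affine, bending_energy=energy, _K=K)


def warp_to_node(closest_species_shape: np.ndarray, ancestral_shape: np.ndarray,
                 probe_points: np.ndarray) -> np.ndarray:
    """Warp probe points (outline/grid) by the TPS carrying the nearest
    species' landmarks onto a reconstructed ancestral configuration."""
    spline = tps_fit(closest_species_shape, ancestral_shape)
    return spline.transform(probe_points)


def deformation_grid(spline: ThinPlateSpline, n: int = 20, margin: float = 0.1):
    """Regular 2D grid over the source bounding box and its warped image;
    for deformation-grid figures."""
    if spline.source.shape[1] != 2:
        raise ValueError("deformation grids are 2D only")
    lo = spline.source.min(axis=0)
    hi = spline.source.max(axis=0)
    pad = margin * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], n)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], n)
    grid = np.array([[x, y] for y in ys for x in xs])
    return grid, spline.transform(grid)
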