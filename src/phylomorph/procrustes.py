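"""Generalized Procrustes Analysis and tangent-space projection.

Superimposition removes position, scale and orientation: configurations are
centred, fixed to unit centroid size, and iteratively rotated to the running
consensus until the consensus stabilizes.  Aligned shapes are then projected
orthogonally onto the tangent space at the consensus, the linearized shape
space in which ordinary multivariate statistics are valid for small
variation.  Centroid sizes (the size proxy used throughout) are recorded
before scaling.

Reflections are disallowed by default: consistently digitized specimens
should never need one, and a mirrored specimen indicates a data error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .landmarks import Dataset, DatasetError

log = logging.getLogger(__name__)

__all__ = ["centroid_size", "opa_align", "gpa_align", "species_means",
           "ProcrustesAlignment"]


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances to the centroid.

    Accepts a LandmarkConfiguration or a bare k x d array.  Scales linearly
    under uniform scaling of the configuration.
    """
    X = np.asarray(getattr(config, "coords", config), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    c = X - X.mean(axis=0)
    cs = float(np.sqrt((c ** 2).sum()))
    if cs == 0.0:
        raise ValueError("all landmarks coincident; centroid size is 0")
    return cs


def opa_align(moving: np.ndarray, target: np.ndarray,
              allow_reflection: bool = False):
    """Ordinary (two-configuration) Procrustes rotation.

    Both inputs are expected centred; returns ``(rotated, distance)`` where
    ``rotated = moving @ R`` with R the orthogonal matrix (det +1 unless
    reflections are allowed) minimizing the summed squared differences, and
    distance is the root summed squared residual.  Degenerate
    (rank-deficient) cross-covariances are resolved deterministically by
    flipping the smallest singular pair.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError("configurations must share k and d")
    H = moving.T @ target
    U, s, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        if s[-1] > 1e-12 * s[0] and np.isclose(s[-1], s[-2]):
            log.warning("opa_align: near-degenerate optimum; deterministic "
                        "smallest-singular-pair flip applied")
        D = np.ones(len(s))
        D[-1] = -1.0
        R = (U * D) @ Vt
    rotated = moving @ R
    dist = float(np.sqrt(((rotated - target) ** 2).sum()))
    return rotated, dist


@dataclass
class ProcrustesAlignment:
    """Result of a Generalized Procrustes Analysis.

    ``aligned`` holds unit-centroid-size superimposed configurations,
    ``consensus`` their arithmetic mean (the GPA fixed point), ``tangent``
    the centred tangent-space coordinates (rows zero-mean over specimens)
    and ``centroid_sizes`` the pre-scaling sizes in length units.
    """

    aligned: np.ndarray            # (n, k, d)
    consensus: np.ndarray          # (k, d)
    centroid_sizes: np.ndarray     # (n,)
    tangent: np.ndarray            # (n, k*d)
    iterations: int
    converged: bool
    specimen_ids: list = field(default_factory=list)
    residual_history: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def d(self) -> int:
        return self.aligned.shape[2]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd
        cols = [f"t{j}" for j in range(self.tangent.shape[1])]
        df = pd.DataFrame(self.tangent, columns=cols)
        df.insert(0, "specimen_id", self.specimen_ids or range(self.n))
        df.insert(1, "centroid_size", self.centroid_sizes)
        return df


def gpa_align(dataset, tol: float = 1e-10, max_iter: int = 100,
              allow_reflection: bool = False) -> ProcrustesAlignment:
    """Generalized Procrustes Analysis with tangent projection.

    Accepts a :class:`Dataset` or an ``(n, k, d)`` array.  Configurations
    are centred and fixed to unit centroid size; the rotate-to-consensus /
    re-average cycle repeats until the consensus moves less than ``tol``
    (Frobenius norm) or ``max_iter`` is hit, in which case the partial
    result is returned with ``converged=False``.  The Procrustes residual
    sum is non-increasing across iterations by construction of the
    alternating minimization.
    """
    if isinstance(dataset, Dataset):
        X = dataset.coords_array()
        ids = dataset.specimen_ids
    else:
        X = np.asarray(dataset, dtype=float)
        ids = [f"spec_{i}" for i in range(X.shape[0])]
    if X.ndim != 3:
        raise DatasetError("expected an (n, k, d) array of configurations")
    n, k, d = X.shape
    if n < 3:
        raise DatasetError("GPA needs at least 3 configurations")

    sizes = np.empty(n)
    aligned = np.empty_like(X)
    for i in range(n):
        c = X[i] - X[i].mean(axis=0)
        sizes[i] = centroid_size(X[i])
        aligned[i] = c / sizes[i]

    consensus = aligned[0].copy()
    residuals = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i], _ = opa_align(aligned[i], consensus,
                                      allow_reflection=allow_reflection)
        new_consensus = aligned.mean(axis=0)
        residuals.append(float(((aligned - new_consensus) ** 2).sum()))
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if it > 1 and delta < tol:
            converged = True
            break
    if not converged:
        log.warning("gpa_align: no convergence in %d iterations", max_iter)

    # canonical orientation: rotate everything so the consensus lies along
    # its principal axes (with deterministic signs); makes the output frame
    # independent of the input configurations' arbitrary orientations
    _, _, Vt = np.linalg.svd(consensus - consensus.mean(axis=0),
                             full_matrices=False)
    R = Vt.T
    for j in range(d):
        col = consensus @ R[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            R[:, j] = -R[:, j]
    if np.linalg.det(R) < 0:
        R[:, -1] = -R[:, -1]
    consensus = consensus @ R
    aligned = aligned @ R

    # orthogonal projection onto the tangent space at the consensus
    cvec = consensus.ravel()
    cunit = cvec / np.linalg.norm(cvec)
    flat = aligned.reshape(n, k * d)
    tangent = flat - np.outer(flat @ cunit, cunit)
    tangent = tangent - tangent.mean(axis=0)

    log.info("gpa_align: n=%d k=%d d=%d iterations=%d converged=%s",
             n, k, d, it, converged)
    return ProcrustesAlignment(aligned=aligned, consensus=consensus,
                               centroid_sizes=sizes, tangent=tangent,
                               iterations=it, converged=converged,
                               specimen_ids=list(ids),
                               residual_history=np.asarray(residuals))


def species_means(alignment: ProcrustesAlignment, species_ids,
                  stage=None, stages=None):
    """Average specimens to species level in tangent space.

    Tangent coordinates are averaged arithmetically within species; centroid
    sizes are averaged on the log scale and exponentiated.  ``stages`` (one
    entry per specimen) with ``stage`` filters to a single life stage;
    species with no specimen at the requested stage are excluded with a
    warning.  Returns ``(species, mean_tangent, mean_sizes)``.
    """
    species_ids = np.asarray(list(species_ids))
    if len(species_ids) != alignment.n:
        raise DatasetError("species_ids must map every specimen")
    keep = np.ones(alignment.n, dtype=bool)
    if stage is not None:
        if stages is None:
            raise ValueError("stage filtering requires per-specimen stages")
        keep = np.asarray(list(stages)) == stage
    all_species = list(dict.fromkeys(species_ids))
    out_species, means, sizes = [], [], []
    for sp in all_species:
        sel = (species_ids == sp) & keep
        if not sel.any():
            log.warning("species_means: %s has no specimen at stage %s; "
                        "excluded", sp, stage)
            continue
        out_species.append(sp)
        means.append(alignment.tangent[sel].mean(axis=0))
        sizes.append(float(np.exp(np.log(alignment.centroid_sizes[sel]).mean())))
    return out_species, np.asarray(means), np.asarray(sizes)
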