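"""Phylogenetic comparative machinery.

Independent contrasts, squared-change parsimony ancestral reconstruction
(unweighted and branch-length-weighted, the latter equal to the maximum
likelihood states under Brownian motion), the multivariate K-statistic of
phylogenetic signal with its permutation test, and Brownian-motion
simulation along a tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .trees import Phylogeny, TreeError

log = logging.getLogger(__name__)

__all__ = [
    "pic",
    "pic_matrix",
    "AncestralEstimates",
    "ancestors_scp",
    "scp_solver",
    "map_size_evolution",
    "PhyloSignalResult",
    "physignal_K",
    "simulate_bm",
    "bm_tip_simulator",
    "evolutionary_rate_matrix",
]


def _as_tip_matrix(tree: Phylogeny, values, names=None) -> np.ndarray:
    """Coerce tip values to an (n_tips, q) array in tip-index order."""
    Y = np.asarray(values, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if names is not None:
        missing = [n for n in tree.tip_labels if n not in set(names)]
        if missing:
            raise TreeError(f"tip values missing for: {missing}")
        order = [list(names).index(lab) for lab in tree.tip_labels]
        Y = Y[order]
    if Y.shape[0] != tree.n_tips:
        raise TreeError(
            f"got {Y.shape[0]} rows of tip values for {tree.n_tips} tips")
    return Y


def pic(tree: Phylogeny, values, names=None) -> np.ndarray:
    """Phylogenetically independent contrasts.

    Standard contrast recursion: at each internal node the difference of the
    two daughter values is divided by the square root of the summed
    (inflation-corrected) daughter branch lengths; the node value is the
    branch-length-weighted average of the daughters and the branch above the
    node is inflated by the product over the sum of daughter lengths.

    Returns an ``(n_tips - 1, q)`` array of contrasts, one per internal node
    in postorder.  Polytomies are resolved (zero-length insertions) first.
    """
    if not tree.is_binary():
        tree = tree.resolve_polytomies()
    Y = _as_tip_matrix(tree, values, names)
    q = Y.shape[1]
    vals = np.zeros((tree.n_nodes, q))
    vals[: tree.n_tips] = Y
    bl = tree.lengths.astype(float).copy()
    eps = 1e-8 * max(tree.tree_depth(), 1.0)
    contrasts = []
    for nd in tree.postorder():
        if nd < tree.n_tips:
            continue
        c1, c2 = tree.children[nd]
        b1, b2 = bl[c1], bl[c2]
        if b1 + b2 <= 0:
            b1 = b2 = eps
        contrasts.append((vals[c1] - vals[c2]) / np.sqrt(b1 + b2))
        vals[nd] = (b2 * vals[c1] + b1 * vals[c2]) / (b1 + b2)
        bl[nd] += b1 * b2 / (b1 + b2)
    return np.asarray(contrasts)


def pic_matrix(tree: Phylogeny) -> np.ndarray:
    """The linear map A with ``pic(tree, Y) = A @ Y`` (contrasts are linear
    in tip values); used to vectorize permutation tests."""
    return pic(tree, np.eye(tree.n_tips))


@dataclass
class AncestralEstimates:
    """Squared-change parsimony estimates at internal nodes.

    ``node_values[i]`` holds the estimate for internal node ``n_tips + i``;
    ``all_values`` stacks observed tips with the estimates so any node id
    indexes directly.
    """

    tree: Phylogeny
    node_values: np.ndarray  # (n_internal, q)
    mode: str
    all_values: np.ndarray = field(repr=False, default=None)  # (n_nodes, q)

    def value(self, node: int) -> np.ndarray:
        return self.all_values[node]


def _scp_system(tree: Phylogeny, mode: str):
    n, m = tree.n_tips, tree.n_nodes - tree.n_tips
    if m == 0:
        raise TreeError("tree has no internal nodes")
    eps = 1e-8 * max(tree.tree_depth(), 1.0)
    L = np.zeros((m, m))
    B = np.zeros((m, n))
    for child in range(tree.n_nodes):
        par = tree.parent[child]
        if par < 0:
            continue
        if mode == "weighted":
            b = tree.lengths[child]
            if b <= 0:
                b = eps
            if b <= 0:
                raise TreeError("all-zero branch lengths; weighted mode singular")
            w = 1.0 / b
        elif mode == "unweighted":
            w = 1.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        pi = par - n
        L[pi, pi] += w
        if child < n:
            B[pi, child] += w
        else:
            ci = child - n
            L[ci, ci] += w
            L[pi, ci] -= w
            L[ci, pi] -= w
    return L, B


def scp_solver(tree: Phylogeny, mode: str = "weighted"):
    """Pre-factorized squared-change parsimony solver.

    Returns a function mapping an ``(n_tips, q)`` tip matrix to the
    ``(n_internal, q)`` internal-node estimates; the tree-dependent linear
    system is factorized once, so repeated calls (e.g. inside simulation
    nulls) cost only a triangular solve.
    """
    L, B = _scp_system(tree, mode)
    lu = lu_factor(L)

    def solve(Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.ndim == 1:
            Y = Y[:, None]
        return lu_solve(lu, B @ Y)

    return solve


def ancestors_scp(tree: Phylogeny, values, mode: str = "weighted",
                  names=None) -> AncestralEstimates:
    """Ancestral states by squared-change parsimony.

    Minimizes the sum over branches of (change)^2 / w with w = 1
    (``unweighted``) or w = branch length (``weighted``).  The weighted
    solution coincides with the ML / GLS ancestral states under Brownian
    motion.  Solved exactly through the tree's Laplacian system.
    """
    Y = _as_tip_matrix(tree, values, names)
    node_values = scp_solver(tree, mode)(Y)
    all_values = np.vstack([Y, node_values])
    return AncestralEstimates(tree=tree, node_values=node_values, mode=mode,
                              all_values=all_values)


def map_size_evolution(tree: Phylogeny, tip_sizes, mode: str = "weighted",
                       names=None) -> AncestralEstimates:
    """Ancestral centroid sizes via squared-change parsimony on log size.

    Sizes must be positive; the reconstruction runs on the log scale (the
    scale on which size evolution is modelled) and estimates are
    exponentiated for reporting, stored alongside tip sizes.
    """
    s = np.asarray(tip_sizes, dtype=float).ravel()
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("centroid sizes must be positive and finite")
    est = ancestors_scp(tree, np.log(s), mode=mode, names=names)
    est.node_values = np.exp(est.node_values)
    est.all_values = np.exp(est.all_values)
    return est


# ---------------------------------------------------------------- K-statistic

@dataclass
class PhyloSignalResult:
    """Multivariate phylogenetic signal (generalized K) with permutation p."""

    K: float
    p_value: float
    n_perm: int
    observed_rank: int
    perm_K: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        return (f"Multivariate phylogenetic signal\n"
                f"  K        = {self.K:.4f}  (Brownian-motion expectation 1)\n"
                f"  p-value  = {self.p_value:.4g}  ({self.n_perm} permutations)\n")


def _kmult_machinery(tree: Phylogeny):
    C = tree.vcv()
    Cinv = np.linalg.inv(C)
    ones = np.ones(tree.n_tips)
    denom_a = ones @ Cinv @ ones
    a_weights = (Cinv @ ones) / denom_a  # phylogenetic mean weights
    n = tree.n_tips
    expected = (np.trace(C) - n / denom_a) / (n - 1)
    return Cinv, a_weights, expected


def _kmult_stat(Y, Cinv, a_weights, expected) -> float:
    a = a_weights @ Y
    D = Y - a
    num = float(np.sum(D * D))
    den = float(np.sum(D * (Cinv @ D)))
    if den <= 0:
        raise ValueError("degenerate phylogenetic covariance")
    return (num / den) / expected


def physignal_K(tree: Phylogeny, values, n_perm: int = 999, seed=None,
                names=None) -> PhyloSignalResult:
    """Multivariate generalized K-statistic of phylogenetic signal.

    K is the ratio of the among-tip mean squared error to the mean squared
    error under the phylogenetic (Brownian) covariance, scaled by its
    Brownian-motion expectation so that E[K] = 1 under BM.  Significance is
    assessed by shuffling whole multivariate tip rows across the tips of the
    tree (preserving trait covariance) and recomputing K; the p-value uses
    the (b+1)/(m+1) convention.
    """
    if tree.n_tips < 4:
        raise TreeError("phylogenetic signal needs at least 4 tips")
    Y = _as_tip_matrix(tree, values, names)
    if np.allclose(Y, Y.mean(axis=0), atol=1e-300):
        raise ValueError("zero among-tip variance; K undefined")
    Cinv, a_w, expected = _kmult_machinery(tree)
    K_obs = _kmult_stat(Y, Cinv, a_w, expected)
    rng = np.random.default_rng(seed)
    perm_K = np.empty(n_perm)
    for i in range(n_perm):
        perm_K[i] = _kmult_stat(Y[rng.permutation(tree.n_tips)], Cinv, a_w,
                                expected)
    b = int(np.sum(perm_K >= K_obs))
    p = (b + 1) / (n_perm + 1)
    log.info("physignal_K: n=%d q=%d K=%.4f p=%.4g (%d perms)",
             Y.shape[0], Y.shape[1], K_obs, p, n_perm)
    return PhyloSignalResult(K=K_obs, p_value=p, n_perm=n_perm,
                             observed_rank=b + 1, perm_K=perm_K)


# ------------------------------------------------------------- BM simulation

def simulate_bm(tree: Phylogeny, rate, root=0.0, seed=None,
                return_nodes: bool = False) -> np.ndarray:
    """Simulate multivariate Brownian motion along the tree.

    Each branch contributes an independent multivariate normal increment
    with covariance ``branch_length * rate``.  ``rate`` may be a scalar, a
    vector of per-trait variances, or a full q x q positive semidefinite
    covariance.  Returns tip values ``(n_tips, q)`` (and all node values if
    requested).
    """
    rate = np.atleast_2d(np.asarray(rate, dtype=float))
    if rate.shape[0] == 1 and rate.shape[1] > 1:
        rate = np.diag(rate.ravel())
    elif rate.shape == (1, 1):
        pass
    q = rate.shape[0]
    if rate.shape != (q, q):
        raise ValueError("rate must be scalar, vector or square covariance")
    if not np.allclose(rate, rate.T):
        raise ValueError("rate covariance must be symmetric")
    w, V = np.linalg.eigh(rate)
    if np.any(w < -1e-10 * max(w.max(), 1.0)):
        raise ValueError("rate covariance must be positive semidefinite")
    sq = V * np.sqrt(np.clip(w, 0, None))  # matrix square root
    root = np.broadcast_to(np.asarray(root, dtype=float).ravel(), (q,))

    rng = np.random.default_rng(seed)
    vals = np.zeros((tree.n_nodes, q))
    vals[tree.root] = root
    Z = rng.standard_normal((tree.n_nodes, q))
    for nd in tree.preorder():
        if nd == tree.root:
            continue
        par = tree.parent[nd]
        vals[nd] = vals[par] + np.sqrt(tree.lengths[nd]) * (sq @ Z[nd])
    if return_nodes:
        return vals[: tree.n_tips], vals
    return vals[: tree.n_tips]


def bm_tip_simulator(tree: Phylogeny, rate):
    """Vectorized Brownian-motion simulator returning tip values only.

    Precomputes the root-to-tip branch incidence so each replicate is a
    single matrix product; used inside simulation-based null distributions
    (convergence, phylogenetic MANOVA) where thousands of replicates are
    drawn on a fixed tree.
    """
    rate = np.atleast_2d(np.asarray(rate, dtype=float))
    if rate.shape == (1, 1):
        q = 1
    else:
        q = rate.shape[0]
    w, V = np.linalg.eigh(rate if rate.shape == (q, q) else np.diag(rate.ravel()))
    if np.any(w < -1e-10 * max(w.max(), 1.0)):
        raise ValueError("rate covariance must be positive semidefinite")
    sq = (V * np.sqrt(np.clip(w, 0, None))).T          # (q, q)
    M = np.zeros((tree.n_tips, tree.n_nodes))
    for t in range(tree.n_tips):
        for nd in tree.path_to_root(t):
            if nd != tree.root:
                M[t, nd] = np.sqrt(tree.lengths[nd])

    def draw(rng) -> np.ndarray:
        Z = rng.standard_normal((tree.n_nodes, q))
        return M @ (Z @ sq)

    return draw


def evolutionary_rate_matrix(tree: Phylogeny, values, names=None) -> np.ndarray:
    """Evolutionary (Brownian-rate) trait covariance from independent
    contrasts: R = U'U / (n - 1), the standard GLS rate estimator."""
    U = pic(tree, values, names)
    return (U.T @ U) / U.shape[0]
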