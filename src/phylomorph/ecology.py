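"""Ecology-shape association tests and ancestral-ecology prediction.

Habitat preference takes one of five states (aquatic, terrestrial,
leaf_litter, fossorial, arboreal).  The association between habitat and
shape scores is tested with a MANOVA (Wilks' lambda, Rao F approximation),
with a phylogenetic variant whose null distribution comes from
Brownian-motion simulation along the tree (labels held fixed), and with
per-axis ANOVAs followed by permutation post hoc pairwise comparisons
(Holm-corrected).  Ancestral ecologies are then predicted from reconstructed
ancestral shape scores with a Gaussian equal-covariance linear discriminant
model yielding class posteriors, validated by leave-one-out
cross-validation on the extant species.

Wilks' lambda and the discriminant model are implemented directly (both run
inside simulation loops and must score arbitrary ancestral points); tests
cross-check them against statsmodels and scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .comparative import bm_tip_simulator, evolutionary_rate_matrix
from .trees import Phylogeny

log = logging.getLogger(__name__)

__all__ = [
    "wilks_lambda",
    "manova_shape_ecology",
    "phylo_manova",
    "anova_posthoc",
    "DiscriminantModel",
    "lda_fit",
    "cross_validate",
    "EcologyPrediction",
    "predict_ancestral_ecology",
]


def _check_groups(labels, min_size=2):
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < min_size]
    if len(small):
        raise ValueError(f"class {small[0]!r} has fewer than {min_size} members")
    return labels, classes


def wilks_lambda(scores: np.ndarray, labels):
    """Wilks' lambda and its Rao F approximation.

    Returns ``(lambda, F, df1, df2, p)``.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels, classes = _check_groups(labels)
    n, m = X.shape
    g = len(classes)
    grand = X.mean(axis=0)
    W = np.zeros((m, m))
    B = np.zeros((m, m))
    for c in classes:
        Xi = X[labels == c]
        mu = Xi.mean(axis=0)
        D = Xi - mu
        W += D.T @ D
        dm = (mu - grand)[:, None]
        B += len(Xi) * (dm @ dm.T)
    lam = float(np.linalg.det(W) / np.linalg.det(W + B))
    # Rao's F approximation
    p_ = m
    q_ = g - 1
    t_ = n - 1 - (p_ + g) / 2.0
    s_ = np.sqrt((p_ ** 2 * q_ ** 2 - 4) / (p_ ** 2 + q_ ** 2 - 5)) \
        if p_ ** 2 + q_ ** 2 - 5 > 0 else 1.0
    df1 = p_ * q_
    df2 = t_ * s_ - df1 / 2.0 + 1.0
    lam_s = lam ** (1.0 / s_)
    F = (1 - lam_s) / lam_s * df2 / df1
    p = float(stats.f.sf(F, df1, df2))
    return lam, float(F), float(df1), float(df2), p


@dataclass
class ManovaResult:
    statistic: float          # Wilks' lambda
    F: float
    df1: float
    df2: float
    p_value: float
    kind: str = "manova"
    n_sim: int = 0

    def summary(self) -> str:
        s = (f"{'Phylogenetic ' if self.kind == 'phylo' else ''}MANOVA "
             f"(Wilks' lambda)\n  lambda = {self.statistic:.4f}\n")
        if self.kind == "phylo":
            s += f"  p (BM simulation, {self.n_sim} sims) = {self.p_value:.4g}\n"
        else:
            s += (f"  F({self.df1:.0f}, {self.df2:.1f}) = {self.F:.3f}, "
                  f"p = {self.p_value:.4g}\n")
        return s


def manova_shape_ecology(scores, labels) -> ManovaResult:
    """Standard MANOVA of shape scores on habitat class."""
    lam, F, df1, df2, p = wilks_lambda(scores, labels)
    return ManovaResult(statistic=lam, F=F, df1=df1, df2=df2, p_value=p)


def phylo_manova(tree: Phylogeny, scores, labels, n_sim: int = 1000,
                 seed=None, names=None) -> ManovaResult:
    """MANOVA with a Brownian-motion phylogenetic null.

    The observed Wilks' lambda is compared with lambdas from ``n_sim``
    BM simulations along the tree (rate matrix from the evolutionary
    covariance of the scores), labels held fixed; smaller lambda means more
    separation, so p = (#{lambda_sim <= lambda_obs} + 1) / (n_sim + 1).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    from .comparative import _as_tip_matrix

    X = _as_tip_matrix(tree, scores, names)
    if names is not None:
        order = [list(names).index(lab) for lab in tree.tip_labels]
        labels = np.asarray(list(labels))[order]
    lam, F, df1, df2, _ = wilks_lambda(X, labels)
    rate = evolutionary_rate_matrix(tree, X)
    draw = bm_tip_simulator(tree, rate)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        lam_s = wilks_lambda(draw(rng), labels)[0]
        if lam_s <= lam:
            count += 1
    p = (count + 1) / (n_sim + 1)
    log.info("phylo_manova: lambda=%.4f p=%.4g (%d sims)", lam, p, n_sim)
    return ManovaResult(statistic=lam, F=F, df1=df1, df2=df2, p_value=p,
                        kind="phylo", n_sim=n_sim)


def anova_posthoc(scores, labels, n_perm: int = 999, seed=None,
                  alpha: float = 0.05):
    """Per-axis one-way ANOVAs plus multivariate post hoc pairwise tests.

    Returns ``(per_axis, pairwise)`` DataFrames.  Pairwise comparisons test
    the Euclidean distance between class mean vectors by permutation of the
    two classes' rows, Holm-corrected across pairs (a conservative default;
    the choice of correction is configurable upstream).
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels, classes = _check_groups(labels)
    rows = []
    for j in range(X.shape[1]):
        groups = [X[labels == c, j] for c in classes]
        F, p = stats.f_oneway(*groups)
        rows.append({"axis": j, "F": float(F), "p": float(p)})
    per_axis = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    pair_rows = []
    for a, b in combinations(classes, 2):
        Xa, Xb = X[labels == a], X[labels == b]
        obs = float(np.linalg.norm(Xa.mean(0) - Xb.mean(0)))
        pooled = np.vstack([Xa, Xb])
        na = len(Xa)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(len(pooled))
            d = np.linalg.norm(pooled[idx[:na]].mean(0)
                               - pooled[idx[na:]].mean(0))
            if d >= obs:
                count += 1
        pair_rows.append({"class_a": a, "class_b": b, "distance": obs,
                          "p": (count + 1) / (n_perm + 1)})
    pairwise = pd.DataFrame(pair_rows)
    from statsmodels.stats.multitest import multipletests

    rej, p_adj, _, _ = multipletests(pairwise["p"], alpha=alpha,
                                     method="holm")
    pairwise["p_holm"] = p_adj
    pairwise["significant"] = rej
    return per_axis, pairwise


# ----------------------------------------------------------------- LDA / DFA

@dataclass
class DiscriminantModel:
    """Gaussian equal-covariance linear discriminant model.

    Class posteriors follow from class means, a pooled within-class
    covariance (regularized toward its diagonal when near-singular) and
    class priors; ``discriminant_axes`` are the canonical axes (at most
    n_classes - 1).
    """

    classes: np.ndarray
    class_means: np.ndarray                # (g, m)
    pooled_within_covariance: np.ndarray   # (m, m)
    priors: np.ndarray                     # (g,)
    discriminant_axes: np.ndarray          # (m, <=g-1)
    _prec: np.ndarray = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Class posterior probabilities for each row of X (sum to 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"basis mismatch: model has {self.n_features} axes, data has "
                f"{X.shape[1]}")
        # log N(x | mu_c, S) + log prior, via the shared precision matrix
        diffs = X[:, None, :] - self.class_means[None, :, :]   # (n, g, m)
        maha = np.einsum("ngm,mk,ngk->ng", diffs, self._prec, diffs)
        loglik = -0.5 * maha + np.log(self.priors)[None, :]
        loglik -= loglik.max(axis=1, keepdims=True)
        post = np.exp(loglik)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.posterior(X), axis=1)]


def lda_fit(scores, labels, prior_policy: str = "proportional",
            cond_threshold: float = 1e10) -> DiscriminantModel:
    """Fit the linear discriminant model.

    ``prior_policy`` is ``proportional`` (class frequencies) or ``uniform``.
    If the pooled within-class covariance has condition number above
    ``cond_threshold`` it is shrunk toward its diagonal by
    lambda = 1e-6 * trace / m (logged); if still singular an error advises
    retaining fewer axes.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    # singleton classes are permitted (their mean is the lone point and they
    # contribute nothing to the pooled scatter) so leave-one-out folds on
    # small classes remain fittable
    labels, classes = _check_groups(labels, min_size=1)
    n, m = X.shape
    g = len(classes)
    if n <= g:
        raise ValueError("need more observations than classes")
    if prior_policy == "proportional":
        priors = np.array([(labels == c).mean() for c in classes])
    elif prior_policy == "uniform":
        priors = np.full(g, 1.0 / g)
    else:
        raise ValueError("prior_policy must be 'proportional' or 'uniform'")

    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    W = np.zeros((m, m))
    for i, c in enumerate(classes):
        D = X[labels == c] - means[i]
        W += D.T @ D
    S = W / (n - g)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > cond_threshold:
        lam = 1e-6 * np.trace(S) / m
        S = S + lam * np.eye(m)
        log.info("lda_fit: pooled covariance condition %.3g; ridge "
                 "regularized (lambda=%.3g)", cond, lam)
    try:
        prec = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise ValueError(
            "pooled covariance singular even after regularization; retain "
            "fewer score axes") from None

    # canonical discriminant axes: eigenvectors of S^-1 B
    grand = (priors[:, None] * means).sum(axis=0) / priors.sum()
    B = np.zeros((m, m))
    for i, c in enumerate(classes):
        dm = (means[i] - grand)[:, None]
        B += (labels == c).sum() * (dm @ dm.T)
    evals, evecs = np.linalg.eig(prec @ B)
    order = np.argsort(evals.real)[::-1][: min(g - 1, m)]
    axes = np.real(evecs[:, order])

    return DiscriminantModel(classes=classes, class_means=means,
                             pooled_within_covariance=S, priors=priors,
                             discriminant_axes=axes, _prec=prec)


@dataclass
class CrossValidationResult:
    accuracy: float
    confusion: pd.DataFrame
    predictions: np.ndarray

    def summary(self) -> str:
        return (f"Leave-one-out cross-validation\n"
                f"  accuracy = {self.accuracy:.3f}\n"
                f"{self.confusion.to_string()}\n")


def cross_validate(scores, labels, prior_policy: str = "proportional"
                   ) -> CrossValidationResult:
    """Leave-one-out cross-validation of the discriminant model.

    Returns overall accuracy and a per-class confusion table whose rows sum
    to the class counts.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    n = len(labels)
    preds = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        keep = np.arange(n) != i
        model = lda_fit(X[keep], labels[keep], prior_policy=prior_policy)
        preds[i] = model.predict(X[i][None, :])[0]
    classes = np.unique(labels)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(labels, preds):
        conf.loc[t, p] += 1
    acc = float((preds == labels).mean())
    log.info("cross_validate: LOO accuracy %.3f over %d specimens", acc, n)
    return CrossValidationResult(accuracy=acc, confusion=conf,
                                 predictions=preds)


@dataclass
class EcologyPrediction:
    """Posterior habitat probabilities for one (ancestral) node."""

    node_id: int
    posterior: np.ndarray
    predicted_class: str
    basis: str = "uncorrected"


def predict_ancestral_ecology(model: DiscriminantModel, ancestral_scores,
                              node_ids=None, basis: str = "uncorrected"
                              ) -> list:
    """Posterior habitat class per reconstructed ancestral node.

    ``ancestral_scores`` must be expressed in the same score basis the model
    was trained on (same number of axes); a mismatch is an error.
    """
    X = np.atleast_2d(np.asarray(ancestral_scores, dtype=float))
    post = model.posterior(X)
    if node_ids is None:
        node_ids = list(range(len(X)))
    out = []
    for i, nid in enumerate(node_ids):
        out.append(EcologyPrediction(
            node_id=nid, posterior=post[i],
            predicted_class=str(model.classes[int(np.argmax(post[i]))]),
            basis=basis))
    return out
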