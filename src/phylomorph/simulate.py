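"""Synthetic landmark studies with the statistical structure the analyses assume.

The generator emulates a squamate-like comparative study end to end: a
pure-birth time-calibrated tree; tip shapes evolving by multivariate
Brownian motion in the tangent space of a 2D skull-outline template, with
fixed-vector habitat-regime shifts (the convergent "fossorial" shift is
planted independently in two distant clades), a planted allometric
component tying shape to log centroid size at a target explained fraction,
and isotropic non-phylogenetic noise; paired stage-10-embryo/adult
configurations following per-clade linear ontogenies with lognormal
development durations; and optional similarity-transform jitter when the
shapes are embedded as raw landmark coordinates (so superimposition has
real work to do).

Every scenario is bit-reproducible from its seed, and the generating truth
(node states, regime labels, planted vectors) is always emitted alongside
the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarks import Dataset, LandmarkConfiguration, write_tps
from .trees import Phylogeny

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "SyntheticStudy",
    "pure_birth_tree",
    "skull_template",
    "similarity_basis",
    "simulate_study",
    "simulate_ecology_mk",
    "simulate_heterochrony",
]

CLASSES = ("terrestrial", "fossorial", "aquatic", "arboreal", "leaf_litter")


def pure_birth_tree(n_tips: int, seed=None, depth: float = 1.0) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree, rescaled to the given root depth.

    Tips are labelled ``t1 .. tn`` in simulation order; the tree is
    ultrametric (all extant tips at the present).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    # forward simulation: each extant lineage splits at rate 1
    parent = {0: -1}
    birth = {0: 0.0}        # time the lineage originated
    alive = [0]
    t = 0.0
    nxt = 1
    while len(alive) < n_tips:
        t += rng.exponential(1.0 / len(alive))
        lin = alive[rng.integers(len(alive))]
        c1, c2 = nxt, nxt + 1
        nxt += 2
        parent[c1] = lin
        parent[c2] = lin
        birth[c1] = birth[c2] = t
        alive.remove(lin)
        alive.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / len(alive))
    # a node's end time is its children's birth; extant tips end at t_end
    children: dict = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    end = {}
    for nd in parent:
        end[nd] = birth[children[nd][0]] if nd in children else t_end

    tips = sorted(nd for nd in parent if nd not in children)
    internals = sorted(nd for nd in parent if nd in children)
    index = {nd: i for i, nd in enumerate(tips)}
    # postorder internal indexing: children before parents; sort by birth desc
    for i, nd in enumerate(sorted(internals, key=lambda n: -birth[n])):
        index[nd] = len(tips) + i
    n_nodes = len(parent)
    par_arr = np.full(n_nodes, -1, dtype=int)
    lengths = np.zeros(n_nodes)
    for nd, p in parent.items():
        if p >= 0:
            par_arr[index[nd]] = index[p]
            lengths[index[nd]] = end[nd] - birth[nd]
    labels = [f"t{i + 1}" for i in range(len(tips))]
    tree = Phylogeny(par_arr, lengths, labels)
    tree.lengths *= depth / tree.tree_depth()
    return tree


def skull_template(k: int = 20) -> np.ndarray:
    """A k-point 2D skull-outline polygon (lateral view), centred with unit
    centroid size.

    A smooth closed outline: long flat snout, domed braincase, jaw line —
    enough anisotropy that rotations/reflections are unambiguous.
    """
    t = np.linspace(0, 2 * np.pi, k, endpoint=False)
    # ellipse modulated to give a snout taper and cranial dome
    rx = 1.0 + 0.35 * np.cos(t) - 0.15 * np.cos(2 * t)
    ry = 0.45 + 0.18 * np.sin(t) + 0.08 * np.sin(2 * t)
    X = np.column_stack([rx * np.cos(t), ry * np.sin(t)])
    X -= X.mean(axis=0)
    X /= np.sqrt((X ** 2).sum())
    return X


def similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (p x 4) of the similarity directions (x/y
    translation, rotation, scaling) at a 2D template; displacements are
    projected off this subspace so planted variation is pure shape."""
    k = template.shape[0]
    x, y = template[:, 0], template[:, 1]
    cols = [
        np.column_stack([np.ones(k), np.zeros(k)]).ravel(),
        np.column_stack([np.zeros(k), np.ones(k)]).ravel(),
        np.column_stack([-y, x]).ravel(),
        template.ravel(),
    ]
    Q, _ = np.linalg.qr(np.column_stack(cols))
    return Q


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    Magnitudes are on the Procrustes (unit-centroid-size) scale and rates
    are per unit tree depth (the root sits at depth 1).
    """

    seed: int = 0
    n_tips: int = 300
    k: int = 20
    d: int = 2
    tree_model: str = "pure_birth"
    bm_sd: float = 0.05              # total Brownian tip SD across all shape dims
    noise_sd_fraction: float = 0.5   # non-phylogenetic noise SD as fraction of bm_sd
    class_shift: float = 0.12        # norm of each non-terrestrial regime shift
    fossorial_shift: float = 0.18    # norm of the convergent fossorial shift
    allometric_fraction: float = 6.0  # target percent of shape variance from size
    size_log_sd: float = 0.35        # BM SD of log centroid size
    size_log_mean: float = 3.0       # mean log size (physical units)
    ontogeny_fraction: float = 0.3   # fraction of species with embryo pairs
    ontogeny_slope: dict = field(default_factory=lambda: {
        "lizard": 0.08, "snake": 0.16})
    ontogeny_size_drop: float = 1.0  # adult minus embryo log size
    duration_log_mean: float = 4.1   # ~60 days
    duration_log_sd: float = 0.25
    jitter: bool = True              # random rotation/translation on embedding

    def __post_init__(self):
        if not (0 <= self.allometric_fraction < 100):
            raise ValueError("allometric_fraction must be in [0, 100)")
        if self.d != 2:
            raise ValueError("the synthetic template is 2D (d=2)")
        if self.tree_model != "pure_birth":
            raise ValueError("only the pure_birth tree model is implemented")


@dataclass
class SyntheticStudy:
    """A generated study: data plus complete generating truth."""

    scenario: SyntheticScenario
    tree: Phylogeny
    dataset: Dataset
    metadata: pd.DataFrame
    tip_tangent: np.ndarray          # (n_tips, k*d) planted tip shape deviations
    tip_log_size: np.ndarray
    node_regimes: np.ndarray         # habitat label per tree node
    node_tangent: np.ndarray         # (n_nodes, k*d) true node shape deviations
    node_log_size: np.ndarray
    shift_vectors: dict              # class -> (k*d,) vector
    allometry_vector: np.ndarray
    fossorial_clades: list           # internal node ids carrying the shift
    snake_clade: int
    ontogeny: pd.DataFrame           # species-level embryo/adult truth
    template: np.ndarray

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for nd in range(self.tree.n_nodes):
            rows.append({
                "node": nd,
                "is_tip": nd < self.tree.n_tips,
                "label": (self.tree.tip_labels[nd]
                          if nd < self.tree.n_tips else ""),
                "regime": self.node_regimes[nd],
                "log_size": self.node_log_size[nd],
            })
        return pd.DataFrame(rows)


def _pick_clade(tree: Phylogeny, rng, lo_frac, hi_frac, taken: set,
                within: set | None = None):
    """A random internal node whose tip set is unused, inside ``within`` if
    given, with size between the given fractions of all tips."""
    depth_order = rng.permutation(np.arange(tree.n_tips, tree.n_nodes))
    n = tree.n_tips
    for nd in depth_order:
        tips = set(tree.descendant_tips(int(nd)))
        if within is not None and not tips <= within:
            continue
        if tips & taken:
            continue
        if lo_frac * n <= len(tips) <= hi_frac * n:
            return int(nd), tips
    return None, set()


def _assign_regimes(tree: Phylogeny, rng):
    """Clade-structured habitat regimes: terrestrial root state, a fossorial
    shift planted independently in one 'snake' and one 'lizard' clade, and
    one clade each of aquatic/arboreal/leaf-litter."""
    n = tree.n_tips
    snake, snake_tips = _pick_clade(tree, rng, 0.25, 0.5, set())
    if snake is None:
        snake, snake_tips = _pick_clade(tree, rng, 0.15, 0.6, set())
    if snake is None:
        raise RuntimeError("could not find a snake-sized clade; reseed")
    lizard_tips = set(range(n)) - snake_tips

    taken: set = set()
    foss1, f1_tips = _pick_clade(tree, rng, 0.04, 0.15, taken, snake_tips)
    taken |= f1_tips
    foss2, f2_tips = _pick_clade(tree, rng, 0.04, 0.15, taken, lizard_tips)
    taken |= f2_tips
    if foss1 is None or foss2 is None:
        raise RuntimeError("could not plant two fossorial clades; reseed")
    others = {}
    for cls in ("aquatic", "arboreal", "leaf_litter"):
        nd, tips = _pick_clade(tree, rng, 0.04, 0.15, taken)
        if nd is None:
            nd, tips = _pick_clade(tree, rng, 2 / n, 0.15, taken)
        if nd is not None:
            others[cls] = nd
            taken |= tips

    regimes = np.array(["terrestrial"] * tree.n_nodes, dtype=object)
    for nd in tree.clade_nodes(foss1) + tree.clade_nodes(foss2):
        regimes[nd] = "fossorial"
    for cls, nd in others.items():
        for m in tree.clade_nodes(nd):
            regimes[m] = cls
    clade = np.array(["lizard"] * tree.n_nodes, dtype=object)
    for nd in tree.clade_nodes(snake):
        clade[nd] = "snake"
    return regimes, clade, [foss1, foss2], snake


def simulate_study(scenario: SyntheticScenario, outdir=None) -> SyntheticStudy:
    """Generate a complete synthetic study (and optionally write its files).

    Tip shape = Brownian motion + habitat-regime shift + allometric
    component + isotropic noise, all in the template's tangent space.  When
    ``outdir`` is given, writes ``landmarks.tps``, ``tree.nwk``,
    ``metadata.csv``, ``ontogeny.csv`` and ``truth.csv``.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    tree = pure_birth_tree(sc.n_tips, seed=rng.integers(0, 2**31 - 1))
    template = skull_template(sc.k)
    p = sc.k * sc.d
    Q = similarity_basis(template)
    proj = np.eye(p) - Q @ Q.T            # tangent-space projector
    p_eff = p - Q.shape[1]

    from .comparative import simulate_bm

    # Brownian shape component (isotropic in tangent space)
    rate = sc.bm_sd ** 2 / p_eff
    _, bm_nodes = simulate_bm(tree, rate * np.eye(p), root=0.0,
                              seed=rng.integers(0, 2**31 - 1),
                              return_nodes=True)
    bm_nodes = bm_nodes @ proj.T

    # habitat regimes and their fixed shift vectors
    regimes, clades, foss_clades, snake = _assign_regimes(tree, rng)
    raw = rng.standard_normal((p, 5)) @ np.eye(5)
    raw = proj @ raw
    Qs, _ = np.linalg.qr(raw)
    shift_vectors = {"terrestrial": np.zeros(p)}
    for i, cls in enumerate(("fossorial", "aquatic", "arboreal",
                             "leaf_litter")):
        mag = sc.fossorial_shift if cls == "fossorial" else sc.class_shift
        shift_vectors[cls] = Qs[:, i] * mag
    shifts_nodes = np.vstack([shift_vectors[r] for r in regimes])

    # log centroid size: scalar BM
    _, ls_nodes = simulate_bm(tree, sc.size_log_sd ** 2, root=0.0,
                              seed=rng.integers(0, 2**31 - 1),
                              return_nodes=True)
    node_log_size = sc.size_log_mean + ls_nodes.ravel()
    s = node_log_size[: tree.n_tips]

    # allometric component scaled for the target explained fraction,
    # measured where the analysis measures it: in contrast space
    beta_dir = proj @ rng.standard_normal(p)
    beta_dir /= np.linalg.norm(beta_dir)
    noise = rng.standard_normal((tree.n_tips, p)) @ proj.T * (
        sc.noise_sd_fraction * sc.bm_sd / np.sqrt(p_eff))
    Y0 = bm_nodes[: tree.n_tips] + shifts_nodes[: tree.n_tips] + noise
    if sc.allometric_fraction > 0:
        from .comparative import pic_matrix

        A = pic_matrix(tree)
        us = A @ s
        ss = float(us @ us)
        ss_rest = float(((A @ Y0) ** 2).sum())
        f = sc.allometric_fraction / 100.0
        c = np.sqrt(f / (1 - f) * ss_rest / ss)
    else:
        c = 0.0
    beta = c * beta_dir
    tip_tangent = Y0 + np.outer(s - s.mean(), beta)
    node_tangent = bm_nodes + shifts_nodes + np.outer(
        node_log_size - s.mean(), beta)
    node_tangent[: tree.n_tips] = tip_tangent

    # ---------------- embed as landmark configurations -------------------
    def embed(tangent_row, log_size, jitter_rng):
        X = template + tangent_row.reshape(sc.k, sc.d)
        X = X * np.exp(log_size)
        if sc.jitter:
            th = jitter_rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            X = X @ R + jitter_rng.uniform(-5, 5, size=2)
        return X

    configs = []
    for i, lab in enumerate(tree.tip_labels):
        configs.append(LandmarkConfiguration(
            specimen_id=f"{lab}__adult", species_id=lab,
            coords=embed(tip_tangent[i], s[i], rng), stage="adult"))

    # ---------------- ontogeny: embryo/adult pairs ------------------------
    onto_dir = proj @ rng.standard_normal(p)
    onto_dir /= np.linalg.norm(onto_dir)
    n_onto = max(4, int(round(sc.ontogeny_fraction * tree.n_tips)))
    snake_tips = [i for i in range(tree.n_tips) if clades[i] == "snake"]
    lizard_tips = [i for i in range(tree.n_tips) if clades[i] == "lizard"]
    half = n_onto // 2
    chosen = (list(rng.choice(snake_tips, min(half, len(snake_tips)),
                              replace=False))
              + list(rng.choice(lizard_tips, min(n_onto - half,
                                                 len(lizard_tips)),
                                replace=False)))
    onto_rows = []
    for i in chosen:
        grp = clades[i]
        slope = sc.ontogeny_slope["snake" if grp == "snake" else "lizard"]
        drop = sc.ontogeny_size_drop * rng.uniform(0.9, 1.1)
        emb_s = s[i] - drop
        emb_tangent = tip_tangent[i] - slope * drop * onto_dir \
            + proj @ rng.standard_normal(p) * 0.002
        configs.append(LandmarkConfiguration(
            specimen_id=f"{tree.tip_labels[i]}__embryo_stage_10",
            species_id=tree.tip_labels[i],
            coords=embed(emb_tangent, emb_s, rng), stage="embryo_stage_10"))
        duration = float(np.exp(rng.normal(sc.duration_log_mean,
                                           sc.duration_log_sd)))
        onto_rows.append({"species_id": tree.tip_labels[i], "group": grp,
                          "embryo_log_size": emb_s, "adult_log_size": s[i],
                          "duration_days": duration,
                          "planted_slope": slope})
    ontogeny = pd.DataFrame(onto_rows)

    metadata = pd.DataFrame({
        "species_id": tree.tip_labels,
        "ecology": regimes[: tree.n_tips],
        "clade": clades[: tree.n_tips],
        "stage": "adult",
    })
    dataset = Dataset(configurations=configs, metadata=metadata)
    study = SyntheticStudy(
        scenario=sc, tree=tree, dataset=dataset, metadata=metadata,
        tip_tangent=tip_tangent, tip_log_size=s, node_regimes=regimes,
        node_tangent=node_tangent, node_log_size=node_log_size,
        shift_vectors=shift_vectors, allometry_vector=beta,
        fossorial_clades=foss_clades, snake_clade=snake, ontogeny=ontogeny,
        template=template)

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_tps(configs, os.path.join(outdir, "landmarks.tps"))
        tree.to_newick(os.path.join(outdir, "tree.nwk"))
        metadata.to_csv(os.path.join(outdir, "metadata.csv"), index=False)
        ontogeny.to_csv(os.path.join(outdir, "ontogeny.csv"), index=False)
        study.truth_frame().to_csv(os.path.join(outdir, "truth.csv"),
                                   index=False)
        log.info("simulate_study: wrote %d configurations to %s",
                 len(configs), outdir)
    return study


def simulate_ecology_mk(tree: Phylogeny, rate_matrix, root_state: int = 0,
                        seed=None, states=None):
    """Continuous-time Markov habitat evolution along the tree.

    ``rate_matrix`` is a generator matrix (rows sum to 0, non-negative
    off-diagonals).  Returns ``(tip_states, node_states)`` as index arrays
    (or labels when ``states`` is given).
    """
    Qm = np.asarray(rate_matrix, dtype=float)
    if Qm.ndim != 2 or Qm.shape[0] != Qm.shape[1]:
        raise ValueError("rate matrix must be square")
    off = Qm - np.diag(np.diag(Qm))
    if np.any(off < 0):
        raise ValueError("negative off-diagonal rate")
    if not np.allclose(Qm.sum(axis=1), 0, atol=1e-10):
        raise ValueError("generator rows must sum to 0")
    rng = np.random.default_rng(seed)
    ns = Qm.shape[0]
    node_states = np.empty(tree.n_nodes, dtype=int)
    node_states[tree.root] = int(root_state)
    for nd in tree.preorder():
        if nd == tree.root:
            continue
        state = node_states[tree.parent[nd]]
        t_left = tree.lengths[nd]
        while True:
            out_rate = -Qm[state, state]
            if out_rate <= 0:
                break
            wait = rng.exponential(1.0 / out_rate)
            if wait >= t_left:
                break
            t_left -= wait
            probs = np.clip(Qm[state], 0, None)
            probs[state] = 0.0
            probs = probs / probs.sum()
            state = int(rng.choice(ns, p=probs))
        node_states[nd] = state
    tips = node_states[: tree.n_tips]
    if states is not None:
        states = np.asarray(states, dtype=object)
        return states[tips], states[node_states]
    return tips, node_states


def simulate_heterochrony(mode: str, n_per_group: int = 30, p: int = 6,
                          seed=None, noise_sd: float = 0.01):
    """Planted two-group heterochrony scenario for the global classifier.

    Groups are 'lizard' (ancestor) and 'snake' (descendant); shape moves
    linearly along a fixed direction with log size.  Modes: acceleration
    (descendant slope doubled, same size ranges and durations),
    hypermorphosis (same slope, size range extended), predisplacement (same
    slope, trajectory offset), paedomorphic_pattern (same slope, descendant
    truncated at mid-ontogeny).  Returns (shapes, log_sizes, groups,
    durations, duration_labels).
    """
    modes = ("acceleration", "hypermorphosis", "predisplacement",
             "paedomorphic_pattern")
    if mode not in modes:
        raise ValueError(f"mode must be one of {modes}")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(p)
    v /= np.linalg.norm(v)
    base_slope = 0.1
    s_lo, s_hi = 2.0, 3.0

    rows, sizes, grps = [], [], []
    for g in ("lizard", "snake"):
        slope = base_slope
        lo, hi = s_lo, s_hi
        offset = np.zeros(p)
        if g == "snake":
            if mode == "acceleration":
                slope = 2 * base_slope
            elif mode == "hypermorphosis":
                hi = s_hi + 0.5
            elif mode == "predisplacement":
                offset = 0.15 * v
            elif mode == "paedomorphic_pattern":
                hi = (s_lo + s_hi) / 2.0
        s = rng.uniform(lo, hi, size=n_per_group)
        # anchor: groups share the shape at the embryonic size floor
        shapes = (np.outer(slope * (s - s_lo), v) + offset
                  + rng.standard_normal((n_per_group, p)) * noise_sd)
        rows.append(shapes)
        sizes.append(s)
        grps += [g] * n_per_group
    durations = np.exp(rng.normal(4.1, 0.25, size=2 * n_per_group))
    return (np.vstack(rows), np.concatenate(sizes), np.array(grps),
            durations, np.array(grps))
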