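"""Rooted phylogenies with branch lengths.

A :class:`Phylogeny` is a lightweight array-backed rooted tree whose tips
index species-level observations.  Nodes are integers: tips are
``0 .. n_tips-1`` (in the order the tree was read or built) and internal
nodes follow, with the root last in preorder position 0.  Branch lengths are
interpreted as divergence-time proxies; zero-length branches are permitted
and adjusted by a small epsilon wherever a division by length occurs.

Newick parsing goes through dendropy; writing is done directly.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


class Phylogeny:
    """Rooted tree with branch lengths and labelled tips.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the parent node of ``i``; the root has parent -1.
    lengths : array of float
        ``lengths[i]`` is the length of the branch above node ``i``
        (ignored for the root).
    tip_labels : sequence of str
        Labels for nodes ``0 .. len(tip_labels)-1``.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray,
                 tip_labels: Sequence[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if self.n_nodes != len(self.lengths):
            raise TreeError("parent and lengths differ in size")
        if len(set(self.tip_labels)) != self.n_tips:
            raise TreeError("duplicated tip label")
        if np.any(self.lengths[self.parent >= 0] < 0):
            raise TreeError("negative branch length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        for i in range(self.n_tips):
            if self.children[i]:
                raise TreeError(f"node {i} is labelled as a tip but has children")
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, source: str, *, is_path: bool | None = None) -> "Phylogeny":
        """Read a single rooted tree from a Newick file or string.

        Absent branch lengths are set to 1 with a logged warning (analyses
        can be run "including or not" time information).  Unlabelled or
        duplicated tips are errors.
        """
        import dendropy

        if is_path is None:
            is_path = "(" not in str(source)
        kwargs = {"path": str(source)} if is_path else {"data": str(source)}
        dtree = dendropy.Tree.get(schema="newick", **kwargs)
        leaves = [lf for lf in dtree.leaf_node_iter()]
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise TreeError("unlabelled tip in Newick input")
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicated tip label in Newick input")

        any_bl = any(e.length is not None for e in dtree.preorder_edge_iter()
                     if e.head_node is not dtree.seed_node)
        if not any_bl:
            log.warning("Newick input carries no branch lengths; using unit lengths")

        idx: dict = {}
        for i, lf in enumerate(leaves):
            idx[lf] = i
        nxt = len(leaves)
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                continue
            idx[nd] = nxt
            nxt += 1
        parent = np.full(nxt, -1, dtype=int)
        lengths = np.zeros(nxt)
        for nd in dtree.preorder_node_iter():
            i = idx[nd]
            if nd.parent_node is not None:
                parent[i] = idx[nd.parent_node]
                bl = nd.edge.length
                lengths[i] = float(bl) if bl is not None else (1.0 if not any_bl else 0.0)
        return cls(parent, lengths, labels)

    def to_newick(self, path: str | None = None) -> str:
        def rec(node: int) -> str:
            if node < self.n_tips:
                s = self.tip_labels[node]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[node]) + ")"
            if node != self.root:
                s += f":{self.lengths[node]:.12g}"
            return s

        out = rec(self.root) + ";"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(out + "\n")
        return out

    # ------------------------------------------------------------ structure
    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"tip {label!r} not in tree") from None

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def is_binary(self) -> bool:
        return all(len(self.children[i]) in (0, 2) for i in range(self.n_nodes))

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        depth = np.zeros(self.n_nodes)
        for nd in self.preorder():
            if nd != self.root:
                depth[nd] = depth[self.parent[nd]] + self.lengths[nd]
        return depth

    def tree_depth(self) -> float:
        return float(self.node_depths()[: self.n_tips].max())

    def path_to_root(self, node: int) -> list[int]:
        out = [node]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def mrca(self, tips: Iterable[int | str]) -> int:
        nodes = [self.tip_index(t) if isinstance(t, str) else int(t) for t in tips]
        common = set(self.path_to_root(nodes[0]))
        for nd in nodes[1:]:
            common &= set(self.path_to_root(nd))
        # deepest shared ancestor
        depth = self.node_depths()
        return int(max(common, key=lambda n: depth[n]))

    def descendant_tips(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd < self.n_tips:
                out.append(nd)
            else:
                stack.extend(self.children[nd])
        return sorted(out)

    def clade_nodes(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(self.children[nd])
        return out

    def vcv(self) -> np.ndarray:
        """Phylogenetic covariance among tips: shared root-to-MRCA path lengths."""
        depth = self.node_depths()
        C = np.zeros((self.n_tips, self.n_tips))
        for nd in self.postorder():
            if nd < self.n_tips:
                C[nd, nd] = depth[nd]
                continue
            groups = [self.descendant_tips(c) for c in self.children[nd]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.asarray(groups[a])
                    ib = np.asarray(groups[b])
                    C[np.ix_(ia, ib)] = depth[nd]
                    C[np.ix_(ib, ia)] = depth[nd]
        return C

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.node_depths()[: self.n_tips]
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    def resolve_polytomies(self) -> "Phylogeny":
        """Return a binary tree, inserting zero-length branches arbitrarily.

        Resolution is deterministic (children kept in stored order).
        """
        if self.is_binary():
            return self
        parent = list(self.parent)
        lengths = list(self.lengths)
        children = [list(c) for c in self.children]
        # iterative: for any node with >2 children, bundle the first two under
        # a new zero-length internal node
        queue = [n for n in range(len(parent)) if len(children[n]) > 2]
        while queue:
            nd = queue.pop()
            while len(children[nd]) > 2:
                a, b = children[nd][0], children[nd][1]
                new = len(parent)
                parent.append(nd)
                lengths.append(0.0)
                children.append([a, b])
                parent[a] = new
                parent[b] = new
                children[nd] = [new] + children[nd][2:]
        log.info("resolved polytomies: %d -> %d nodes", self.n_nodes, len(parent))
        return Phylogeny(np.array(parent), np.array(lengths), self.tip_labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


def read_newick(path: str) -> Phylogeny:
    """Read a rooted phylogeny from a Newick file."""
    return Phylogeny.from_newick(path, is_path=True)
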