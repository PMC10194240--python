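"""Neighbor-joining trees over lysin protein distances.

Supports the two-group separation claim for NLPC/P60 proteins: pairwise
distances are 1 − identity from a global alignment, the tree is classical
neighbor joining (Q-matrix selection with the Studier–Keppler update,
deterministic lowest-index tie break), and a grouping is "separated" when
some tree edge induces exactly that leaf bipartition.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from talscan.align import alignment_identity, global_align

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """A node of an (un)rooted tree; leaves carry labels."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree represented with an arbitrary internal node as root."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return self.root.leaves()

    def edges(self) -> list[tuple[frozenset[str], float]]:
        """All edges as (leaf set below the edge, branch length)."""
        out: list[tuple[frozenset[str], float]] = []

        def walk(node: TreeNode) -> None:
            for child, length in node.children:
                out.append((frozenset(child.leaves()), length))
                walk(child)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return _quote_label(node.label or "")
            inner = ",".join(f"{fmt(c)}:{ln:.6f}" for c, ln in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;'\[\]]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def pairwise_distance(a: str, b: str) -> float:
    """1 − identity over aligned columns (dual-gap columns excluded)."""
    if not a or not b:
        raise ValueError("pairwise_distance requires non-empty sequences")
    _, ga, gb = global_align(a, b)
    return 1.0 - alignment_identity(ga, gb)


def distance_matrix(labels: list[str], sequences: list[str]) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(sequences[i], sequences[j])
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical neighbor joining.

    Q-matrix pair selection, Studier–Keppler distance update, negative branch
    length estimates clamped to zero (amount logged).  Ties in Q are broken
    by the lowest index pair, making the output deterministic.  The final
    three nodes are joined at one internal node, so the result is unrooted
    with internal nodes of degree 3.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor_joining requires at least 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(label=lbl) for lbl in dm.labels]
    active = list(range(n))

    clamped_total = 0.0
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        i_loc, j_loc = divmod(int(flat), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]

        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        for name, val in (("left", li), ("right", lj)):
            if val < 0:
                clamped_total += -val
        li, lj = max(li, 0.0), max(lj, 0.0)

        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_idx = d.shape[0]
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, : new_idx] = new_row
        d[: new_idx, new_idx] = new_row
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lengths = []
    for val in (la, lb, lc):
        if val < 0:
            clamped_total += -val
        lengths.append(max(val, 0.0))
    if clamped_total > 0:
        logger.info("neighbor_joining clamped %.6g of negative branch length", clamped_total)
    root = TreeNode(children=[(nodes[a], lengths[0]), (nodes[b], lengths[1]), (nodes[c], lengths[2])])
    return PhyloTree(root=root)


def two_group_separation(
    tree: PhyloTree, labels_to_group: dict[str, str]
) -> tuple[bool, frozenset[str] | None]:
    """Does some tree edge induce exactly the given two-group bipartition?

    Every leaf must be mapped to one of exactly two group labels.  Returns
    (separated, the leaf set on one side of the splitting edge or None).
    """
    leaves = set(tree.leaf_labels())
    if set(labels_to_group) != leaves:
        raise ValueError("labels_to_group must map every leaf exactly")
    groups = sorted(set(labels_to_group.values()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    side1 = frozenset(l for l, g in labels_to_group.items() if g == groups[0])
    side2 = frozenset(leaves) - side1
    for clade, _length in tree.edges():
        if clade == side1 or clade == side2:
            return True, clade
    return False, None


def additive_matrix_from_tree(tree: PhyloTree) -> DistanceMatrix:
    """Path-length distances between all leaf pairs (for additivity checks)."""
    # collect leaf -> root path lengths via recursion
    paths: dict[str, dict[str, float]] = {}

    def walk(node: TreeNode, acc: list[tuple[str, float]]) -> None:
        if node.is_leaf:
            paths[node.label or ""] = {nid: ln for nid, ln in acc}
            return
        nid = str(id(node))
        for child, ln in node.children:
            walk(child, acc + [(nid + "/" + str(id(child)), ln)])

    walk(tree.root, [])
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pi, pj = paths[labels[i]], paths[labels[j]]
        shared = set(pi) & set(pj)
        dist = sum(pi.values()) + sum(pj.values()) - 2 * sum(pi[e] for e in shared)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d)
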