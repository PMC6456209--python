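"""Sequence-structure distances, neighbor-joining and bootstrap supports.

Distances are computed on the 12-letter sequence-structure encoding: the
p-distance is the fraction of mismatching co-ungapped columns, and the
``poisson-12`` model applies the Poisson-style multiple-hit correction for a
12-state alphabet, d = -(11/12) ln(1 - (12/11) p), capped (and flagged) at a
configurable maximum when p approaches saturation.  The tree is built with
the canonical Saitou-Nei neighbor-joining algorithm; column-resampling
pseudo-replicates give bootstrap supports, reported on the internal edges of
the full-data tree (a majority-rule consensus is available as an alternate
output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import GAP, LETTERS, StructuralAlignment

__all__ = [
    "DistanceMatrix",
    "Node",
    "Tree",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_consensus",
    "majority_rule_consensus",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T) or np.diag(v).any():
            raise ValueError("distances must be symmetric with zero diagonal")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and non-negative")

    def get(self, x: str, y: str) -> float:
        return float(self.values[self.ids.index(x), self.ids.index(y)])


class Node:
    """One node of an (un)rooted tree; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name: str = "", length: float = 0.0, support: Optional[int] = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


class Tree:
    """Unrooted tree serialized with a basal trifurcation."""

    def __init__(self, root: Node):
        self.root = root

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def to_newick(self) -> str:
        names = self.leaf_names
        if not names:
            raise ValueError("cannot serialize an empty tree")
        if any(not n for n in names):
            raise ValueError("every leaf must be labelled")

        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{_fmt_len(node.length)}"
            inner = ",".join(fmt(ch) for ch in node.children)
            label = "" if node.support is None else str(int(round(node.support)))
            return f"({inner}){label}:{_fmt_len(node.length)}"

        inner = ",".join(fmt(ch) for ch in self.root.children)
        label = "" if self.root.support is None else str(int(round(self.root.support)))
        return f"({inner}){label};"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out.add(side)
            return below

        for ch in self.root.children:
            walk(ch)
        return out

    def internal_edges(self) -> list[Node]:
        """Internal (non-root, non-leaf) nodes, i.e. supported edges."""
        out: list[Node] = []

        def walk(node: Node, is_root: bool) -> None:
            if not node.is_leaf and not is_root:
                out.append(node)
            for ch in node.children:
                walk(ch, False)

        walk(self.root, True)
        return out


def _fmt_len(x: float) -> str:
    return f"{x:.6f}".rstrip("0").rstrip(".") or "0"


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_LETTER_INDEX = {ch: k for k, ch in enumerate(LETTERS)}
_POISSON_STATES = 12


def _row_matrix(alignment: StructuralAlignment) -> np.ndarray:
    """(n_records, n_columns) letter indices with -1 marking gaps."""
    mat = np.empty((len(alignment.ids), alignment.n_columns), dtype=np.int8)
    for r, rid in enumerate(alignment.ids):
        row = alignment.row(rid)
        mat[r] = [(-1 if ch == GAP else _LETTER_INDEX[ch]) for ch in row]
    return mat


def _distances_from_rows(
    rows: np.ndarray, ids: Sequence[str], model: str, max_distance: float
) -> DistanceMatrix:
    n = rows.shape[0]
    values = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    k = _POISSON_STATES
    for a in range(n):
        for b in range(a + 1, n):
            mask = (rows[a] >= 0) & (rows[b] >= 0)
            tot = int(mask.sum())
            if tot == 0:
                raise ValueError(f"no co-ungapped columns for pair ({ids[a]}, {ids[b]})")
            p = float((rows[a][mask] != rows[b][mask]).sum()) / tot
            if model == "p-distance":
                d = p
            elif model == "poisson-12":
                arg = 1.0 - p * k / (k - 1)
                if arg <= 0:
                    d = max_distance
                    saturated.append((ids[a], ids[b]))
                else:
                    d = min(-(k - 1) / k * math.log(arg), max_distance)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            values[a, b] = values[b, a] = d
    return DistanceMatrix(list(ids), values, saturated)


def distance_matrix(
    alignment: StructuralAlignment, model: str = "poisson-12", max_distance: float = 5.0
) -> DistanceMatrix:
    """Pairwise distances on the encoded alphabet (see module docstring)."""
    if len(alignment.ids) < 3:
        raise ValueError("need >= 3 records for a distance matrix")
    return _distances_from_rows(_row_matrix(alignment), alignment.ids, model, max_distance)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical Saitou-Nei NJ.

    Ties in the Q-criterion are broken toward the lexicographically smallest
    joined pair (clusters compared by their smallest leaf name); negative
    branch lengths are clamped to zero with the deficit moved to the sister
    branch.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("NJ needs >= 3 records")
    D = dm.values.astype(float).copy()
    nodes: list[Node] = [Node(name) for name in ids]
    reps: list[str] = list(ids)  # smallest leaf name per cluster, for ties
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]
        # grow matrix by one row/col for the new cluster
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            D[k, x] = D[x, k] = 0.5 * (D[i, x] + D[j, x] - D[i, j])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    root = Node()
    nodes[i].length = max(0.0, 0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].length = max(0.0, 0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].length = max(0.0, 0.5 * (D[i, k] + D[j, k] - D[i, j]))
    order = sorted((i, j, k), key=lambda x: reps[x])
    root.children = [nodes[x] for x in order]
    return Tree(root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_consensus(
    alignment: StructuralAlignment,
    replicates: int = 1000,
    seed: int = 0,
    model: str = "poisson-12",
    max_distance: float = 5.0,
) -> Tree:
    """NJ tree from the full alignment with bootstrap supports (0-100) on
    its internal edges, from column-resampling pseudo-replicates."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(alignment.ids) < 4:
        raise ValueError("bootstrap supports need >= 4 records")
    ids = alignment.ids
    rows = _row_matrix(alignment)
    full_tree = neighbor_joining(_distances_from_rows(rows, ids, model, max_distance))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    ncol = rows.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = neighbor_joining(_distances_from_rows(rows[:, cols], ids, model, max_distance))
        for bip in rep.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    _attach_supports(full_tree, counts, replicates)
    full_tree._bipartition_counts = counts  # kept for consensus building
    full_tree._replicates = replicates
    return full_tree


def _attach_supports(tree: Tree, counts: dict[frozenset, int], replicates: int) -> None:
    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)

    def walk(node: Node, is_root: bool) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(ch, False) for ch in node.children))
        if not is_root and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if anchor not in below else all_leaves - below
            node.support = round(100.0 * counts.get(side, 0) / replicates)
        return below

    walk(tree.root, True)


def majority_rule_consensus(tree: Tree) -> Tree:
    """Majority-rule (>50%) consensus from a bootstrapped tree's replicate
    bipartition counts; topology only (branch lengths zero)."""
    counts = getattr(tree, "_bipartition_counts", None)
    reps = getattr(tree, "_replicates", None)
    if counts is None:
        raise ValueError("tree has no bootstrap bipartition counts")
    names = sorted(tree.leaf_names)
    keep = [(bip, c) for bip, c in counts.items() if c * 2 > reps]
    keep.sort(key=lambda t: (-len(t[0]), -t[1], sorted(t[0])))
    root = Node()
    leaf_nodes = {nm: Node(nm) for nm in names}
    # place each majority bipartition as an internal node, largest first
    containers: list[tuple[frozenset, Node]] = [(frozenset(names), root)]
    for bip, c in keep:
        candidates = [(len(fs), k) for k, (fs, _) in enumerate(containers) if bip < fs]
        parent = containers[min(candidates)[1]][1] if candidates else root
        node = Node(support=round(100.0 * c / reps))
        parent.children.append(node)
        containers.append((bip, node))
    # attach leaves to the smallest container that includes them
    for nm in names:
        best_fs, best_nd = None, root
        for fs, nd in containers:
            if nm in fs and (best_fs is None or len(fs) < len(best_fs)):
                best_fs, best_nd = fs, nd
        best_nd.children.append(leaf_nodes[nm])
    return Tree(root)
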