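"""Distance-based phylogenetic placement with bootstrap support.

Distances are Kimura-2-parameter (transitions and transversions weighted
separately), trees are built with the Saitou-Nei Neighbor-Joining algorithm
(deterministic tie-breaking by taxon-label order), and support values come
from site-resampling bootstrap replicates whose split frequencies are mapped
onto the point-estimate tree.  NJ is exact on additive distance matrices,
which the test suite exploits as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

_CODE = {b: i for i, b in enumerate("ACGT")}
_PURINES = {"A", "G"}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def k2p_distance(a: str, b: str) -> float:
    """Kimura-2-parameter distance between two aligned sequences.

    Sites where either sequence has a gap or N are excluded pairwise.
    Returns NaN when the formula saturates (log argument <= 0).
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    valid = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _CODE or y not in _CODE:
            continue
        valid += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if valid == 0:
        return float("nan")
    P, Q = ts / valid, tv / valid
    return k2p_from_fractions(P, Q)


def k2p_from_fractions(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal.

    Triangle-inequality violations are permitted (NJ tolerates them).
    """

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def __getitem__(self, pair) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


def distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    taxa = list(alignment)
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = k2p_distance(alignment[taxa[i]], alignment[taxa[j]])
    return DistanceMatrix(taxa, m)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: Optional[str] = None  # leaf label; None for internal nodes
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root (trifurcation)."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def newick(self, supports: bool = True) -> str:
        def fmt(node: TreeNode, length: Optional[float]) -> str:
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = ""
                if supports and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{max(length, 0.0):.6f}"  # negative NJ branches clamp to 0

        return fmt(self.root, None) + ";"

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each encoded as the leaf set on the side
        not containing the alphabetically first taxon."""
        anchor = min(self.leaves())
        all_leaves = frozenset(self.leaves())
        out = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root)
        return out

    def split_nodes(self) -> dict[frozenset, TreeNode]:
        anchor = min(self.leaves())
        all_leaves = frozenset(self.leaves())
        nodes = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                nodes[side] = node
            return below

        walk(self.root)
        return nodes


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken deterministically by the sorted labels of the two
    candidate nodes, so permuting the input taxa leaves the unrooted
    topology invariant.
    """
    n = len(m.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in m.taxa}
    labels = list(m.taxa)
    d = {(a, b): m.values[i, j] for i, a in enumerate(labels) for j, b in enumerate(labels)}
    next_internal = 0
    while len(labels) > 3:
        r = {a: sum(d[(a, b)] for b in labels if b != a) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (len(labels) - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    pair = (a, b)
        a, b = pair
        dab = d[(a, b)]
        va = 0.5 * dab + (r[a] - r[b]) / (2.0 * (len(labels) - 2))
        vb = dab - va
        new_label = f"_nj{next_internal}"
        next_internal += 1
        parent = TreeNode(children=[(nodes[a], va), (nodes[b], vb)])
        nodes[new_label] = parent
        for c in labels:
            if c in (a, b):
                continue
            d[(new_label, c)] = d[(c, new_label)] = 0.5 * (
                d[(a, c)] + d[(b, c)] - dab
            )
        d[(new_label, new_label)] = 0.0
        labels = [c for c in labels if c not in (a, b)] + [new_label]
    # final trifurcation
    a, b, c = labels
    va = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    vb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    vc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    root = TreeNode(children=[(nodes[a], va), (nodes[b], vb), (nodes[c], vc)])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: dict[str, str], n_reps: int, seed: int = 0
) -> PhyloTree:
    """Site-resampling bootstrap; supports are attached to the point tree.

    Site patterns are compressed and replicates drawn as multinomial counts
    over the unique patterns, so each replicate's pairwise K2P distances are
    pattern-count sums rather than per-site loops.
    """
    if not alignment:
        raise ValueError("empty alignment")
    taxa = sorted(alignment)
    point = nj_tree(distance_matrix({t: alignment[t] for t in taxa}))
    if n_reps <= 0:
        return point
    L = len(next(iter(alignment.values())))
    mat = np.zeros((len(taxa), L), dtype=np.int8)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, t in enumerate(taxa):
        seq = alignment[t].upper()
        if len(seq) != L:
            raise ValueError("alignment rows differ in length")
        mat[i] = [code.get(ch, 4) for ch in seq]
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    npat = patterns.shape[1]
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    valid = np.zeros((len(pairs), npat), dtype=bool)
    is_ts = np.zeros((len(pairs), npat), dtype=bool)
    is_tv = np.zeros((len(pairs), npat), dtype=bool)
    purine = np.isin(patterns, (0, 2))
    for k, (i, j) in enumerate(pairs):
        ok = (patterns[i] < 4) & (patterns[j] < 4)
        diff = ok & (patterns[i] != patterns[j])
        valid[k] = ok
        is_ts[k] = diff & (purine[i] == purine[j])
        is_tv[k] = diff & (purine[i] != purine[j])
    rng = np.random.default_rng(seed)
    split_hits: dict[frozenset, int] = {s: 0 for s in point.splits()}
    n = len(taxa)
    for _ in range(n_reps):
        w = rng.multinomial(counts.sum(), counts / counts.sum())
        vm = valid @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(vm > 0, (is_ts @ w) / vm, 0.0)
            Q = np.where(vm > 0, (is_tv @ w) / vm, 0.0)
        vals = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            dist = k2p_from_fractions(float(P[k]), float(Q[k]))
            if math.isnan(dist):
                dist = 5.0  # saturated replicate distance: effectively infinite
            vals[i, j] = vals[j, i] = dist
        rep = nj_tree(DistanceMatrix(list(taxa), vals))
        rep_splits = rep.splits()
        for s in split_hits:
            if s in rep_splits:
                split_hits[s] += 1
    for side, node in point.split_nodes().items():
        node.support = 100.0 * split_hits[side] / n_reps
    return point


def clade_support(tree: PhyloTree, leaves: Sequence[str]) -> Optional[float]:
    """Bootstrap support of the split isolating ``leaves``, if present."""
    anchor = min(tree.leaves())
    all_leaves = frozenset(tree.leaves())
    side = frozenset(leaves)
    if anchor in side:
        side = all_leaves - side
    node = tree.split_nodes().get(side)
    return node.support if node is not None else None
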