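"""Distance-based family clustering: pairwise alignment distances,
neighbor joining, bootstrap supports, newick export.

Pairwise identity distances (1 - identities / alignment length, from a
global Needleman-Wunsch alignment with match +1, mismatch 0, linear
gap -1) feed canonical Saitou-Nei neighbor joining with a
deterministic label-order tie-break. Bootstrap supports come from
column-resampled replicates of an ungapped alignment (e.g. anchored
equal-length repeat units): each replicate's pairwise identity matrix
is re-clustered and an internal edge's support is the percentage of
replicates containing its bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align


# ---------------------------------------------------------------------------
# distances

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def pairwise_distance(a: str, b: str) -> float:
    """Global-alignment identity distance between two sequences."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner().align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return 1.0 - counts.identities / aln.length


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("asymmetric distance matrix")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("nonzero diagonal")
        if (m < -1e-12).any():
            raise ValueError("negative distances")
        self.matrix = m

    @classmethod
    def from_sequences(cls, sequences: dict) -> "DistanceMatrix":
        labels = list(sequences)
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pairwise_distance(sequences[labels[i]],
                                                      sequences[labels[j]])
        return cls(labels=labels, matrix=m)

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for lab, row in zip(self.labels, self.matrix):
            lines.append(lab + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def identity_distance_matrix(aligned: dict,
                             columns: Sequence[int] | None = None
                             ) -> DistanceMatrix:
    """p-distances over an ungapped alignment, optionally on a column
    subsample (used by the bootstrap)."""
    labels = list(aligned)
    seqs = [aligned[lab] for lab in labels]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    idx = list(range(length)) if columns is None else list(columns)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = sum(1 for c in idx if seqs[i][c] == seqs[j][c])
            m[i, j] = m[j, i] = 1.0 - same / len(idx)
    return DistanceMatrix(labels=labels, matrix=m)


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    """Rootless-tree node; branch length is the edge to the parent."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list:
        return [leaf.name for leaf in self.leaves()]

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


def bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of the leaf set, as canonical frozensets
    of frozensets (unrooted comparison)."""
    all_leaves = frozenset(tree.leaf_names())
    splits = set()

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        clade = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(clade) < len(all_leaves) - 1:
            splits.add(frozenset([clade, all_leaves - clade]))
        return clade

    for child in tree.children:
        walk(child)
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken deterministically by the sorted
    pair of node labels (internal nodes inherit their smallest leaf
    label), so identical inputs give identical trees.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >=3 labels")
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    keys = list(dm.labels)                      # tie-break keys
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent = TreeNode(children=[ni, nj_])
        # new row: distances to the joined node
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    a, b, c = active
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    nodes[a].length = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    nodes[b].length = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    nodes[c].length = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    return root


def bootstrap_support(aligned: dict, n_replicates: int = 2000,
                      seed: int | None = None) -> TreeNode:
    """NJ tree of an ungapped alignment with bootstrap edge supports.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal edge of the full-alignment tree is the
    percentage of replicate trees containing its bipartition. Fixed
    seeds give bit-reproducible supports.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    length = len(next(iter(aligned.values())))
    tree = nj_tree(identity_distance_matrix(aligned))
    counts: dict = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        rep = nj_tree(identity_distance_matrix(aligned, columns=cols))
        for split in bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1

    all_leaves = frozenset(tree.leaf_names())

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        clade = frozenset().union(*(annotate(c) for c in node.children))
        if 1 < len(clade) < len(all_leaves) - 1:
            split = frozenset([clade, all_leaves - clade])
            node.support = 100.0 * counts.get(split, 0) / n_replicates
        return clade

    for child in tree.children:
        annotate(child)
    return tree
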