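"""Levenshtein distances and average-linkage (UPGMA) clustering of CDR3 sets.

Distances between CDR3 amino-acid sequences are plain Levenshtein edit
distances (0 for a match, 1 for a mismatch or indel); paired receptors are
compared as the *sum* of the alpha and beta distances, which is again a
metric.  Trees are built by unweighted average linkage: at every step the
pair of clusters with the minimal average inter-cluster distance is merged
and the merge height is that average.

Merge ties are broken deterministically: leaves carry ids 0..n-1 in input
order, internal nodes are numbered n, n+1, ... in merge order, and among
equally distant cluster pairs the one with the lexicographically smallest
(min id, max id) is merged first.  This makes runs bit-reproducible; linkage
heights are unaffected by the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import edlib
import numpy as np

from .io_repertoire import DegenerateInputError


def levenshtein(a: str, b: str) -> int:
    """Minimal number of substitutions/insertions/deletions turning a into b."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered id list."""

    ids: list[str]
    d: np.ndarray  # square, symmetric, zero diagonal
    metric: str = "levenshtein"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")

    @property
    def n(self) -> int:
        return len(self.ids)


def pairwise_distances(
    items: Sequence[str] | Sequence[tuple[str, str]],
    ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise Levenshtein distance matrix over sequences or sequence pairs.

    For ``(alpha, beta)`` pairs the distance is the sum of the per-chain
    Levenshtein distances.
    """
    n = len(items)
    if n < 2:
        raise DegenerateInputError("need at least 2 items for a distance matrix")
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    paired = isinstance(items[0], (tuple, list))
    d = np.zeros((n, n))
    if paired:
        alphas = [it[0] for it in items]
        betas = [it[1] for it in items]
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = (levenshtein(alphas[i], alphas[j])
                                     + levenshtein(betas[i], betas[j]))
        metric = "paired_sum"
    else:
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = levenshtein(items[i], items[j])
        metric = "levenshtein"
    return DistanceMatrix(ids=ids, d=d, metric=metric)


@dataclass
class DendrogramNode:
    """Binary-merge tree node; leaves have height 0 and two-child internals
    carry the average-linkage merge height."""

    node_id: int
    height: float
    children: tuple["DendrogramNode", "DendrogramNode"] | tuple[()] = ()
    leaf_ids: tuple[str, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["DendrogramNode"]:
        """Depth-first, root first (pre-order)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


def upgma(matrix: DistanceMatrix) -> DendrogramNode:
    """Unweighted average-linkage agglomeration of a distance matrix.

    Inter-cluster distances are the averages of the original leaf-to-leaf
    distances; they are maintained as exact sums and divided by the pair
    count on access, so for integer inputs (the Levenshtein case) equal
    averages compare exactly equal and the documented tie-break is
    well-defined.  Raises on non-finite distances.
    """
    n = matrix.n
    if n < 2:
        raise DegenerateInputError("need at least 2 leaves")
    if not np.all(np.isfinite(matrix.d)):
        raise ValueError("non-finite distances")

    S = matrix.d.astype(float).copy()  # sums of leaf-pair distances
    A = matrix.d.astype(float).copy()  # averages = S / (size_i * size_j)
    np.fill_diagonal(A, np.inf)
    active = np.ones(n, dtype=bool)
    cid = np.arange(n)          # cluster id currently held by each slot
    size = np.ones(n)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(node_id=i, height=0.0, leaf_ids=(matrix.ids[i],))
        for i in range(n)
    }
    row_min = A.min(axis=1)
    next_id = n

    for _ in range(n - 1):
        m = row_min[active].min()
        # all slot pairs realizing the minimum; break ties on (min id, max id)
        best = None
        for i in np.flatnonzero(active & (row_min == m)):
            for j in np.flatnonzero(active & (A[i] == m)):
                key = (min(cid[i], cid[j]), max(cid[i], cid[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        a, b = nodes[cid[i]], nodes[cid[j]]
        node = DendrogramNode(
            node_id=next_id,
            height=float(m),
            children=(a, b) if a.node_id < b.node_id else (b, a),
            leaf_ids=a.leaf_ids + b.leaf_ids,
        )
        nodes[next_id] = node

        old_col_i = A[:, i].copy()
        old_col_j = A[:, j].copy()
        # merged cluster into slot i: sums add exactly; slot j dies
        new_sum = S[i] + S[j]
        new_size = size[i] + size[j]
        S[i] = new_sum
        S[:, i] = new_sum
        with np.errstate(invalid="ignore"):
            new_avg = new_sum / (new_size * size)
        A[i] = new_avg
        A[:, i] = new_avg
        A[i, i] = np.inf
        A[j, :] = np.inf
        A[:, j] = np.inf
        active[j] = False
        size[i] = new_size
        cid[i] = next_id
        next_id += 1

        A[i, ~active] = np.inf
        row_min[i] = A[i].min()
        # averages never fall below the smaller constituent, so only rows
        # whose minimum sat in column i or j can go stale
        stale = active & ((row_min == old_col_i) | (row_min == old_col_j))
        stale[i] = False
        for k in np.flatnonzero(stale):
            row_min[k] = A[k].min()

    return nodes[next_id - 1]


def cut_tree(root: DendrogramNode, height: float) -> list[tuple[str, ...]]:
    """Cut the dendrogram: maximal subtrees with node height <= ``height``.

    Returns disjoint clusters of leaf ids covering all leaves; singletons are
    allowed (leaves have height 0).
    """
    if height < 0:
        raise ValueError("cut height must be >= 0")
    clusters: list[tuple[str, ...]] = []

    def descend(node: DendrogramNode) -> None:
        if node.height <= height:
            clusters.append(node.leaf_ids)
        else:
            for child in node.children:
                descend(child)

    descend(root)
    return clusters


def to_newick(root: DendrogramNode) -> str:
    """Serialize a dendrogram to Newick with heights as branch lengths."""

    def fmt(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.leaf_ids[0]}:{length:g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{length:g}"

    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"
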