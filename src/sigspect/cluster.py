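"""Cosine-similarity distances, UPGMA trees, and double clustering.

Samples (or signatures) are compared by cosine similarity of their
nonnegative count/exposure vectors; distance = 1 - similarity, which lies
in [0, 1]. Trees are built with UPGMA (unweighted pair-group method with
arithmetic mean): at every step the closest pair of clusters merges, and
the distance between clusters is the unweighted mean over all cross pairs
of *original* leaf distances — implemented incrementally via the
size-weighted Lance–Williams update, which is algebraically identical.

Determinism conventions (the method itself does not fix them):

* ties on the minimum distance are broken by merging the pair whose
  (smaller representative index, larger representative index) is
  lexicographically least, where a cluster's representative is the
  smallest original leaf index it contains;
* at each internal node the child containing the smaller original index
  is placed on the left, so leaf order is reproducible.

Each node is annotated with the merge distance, the corresponding
cluster-level cosine similarity (1 - merge distance), and the total
mutation count of the samples beneath it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u.v / (|u||v|) of two nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


@dataclass
class DistanceMatrix:
    """Symmetric cosine distance matrix with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")


def distance_matrix(matrix: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    """Pairwise cosine distances (1 - similarity) between the rows of a
    nonnegative matrix. An all-zero row is an error naming the id."""
    matrix = np.asarray(matrix, dtype=float)
    ids = list(ids)
    if matrix.ndim != 2 or matrix.shape[0] != len(ids):
        raise ValueError("matrix rows must match ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    norms = np.linalg.norm(matrix, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero row for id {ids[zero[0]]!r}")
    unit = matrix / norms[:, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    d = 1.0 - sim
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, d=d)


@dataclass
class ClusterNode:
    """Node of a UPGMA merge tree.

    Leaves carry ``sample_id``; internal nodes carry the merged children,
    the average-linkage ``merge_distance`` and ``similarity`` (1 - merge
    distance). Every node carries the total mutation count of the leaf
    samples beneath it.
    """

    total_mutations: float
    sample_id: str | None = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    merge_distance: float = 0.0
    similarity: float = 1.0
    _min_leaf: int = 0  # smallest original leaf index underneath

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()

    def leaf_order(self) -> list[str]:
        return [leaf.sample_id for leaf in self.leaves()]


def upgma(
    dmat: DistanceMatrix,
    totals: Mapping[str, float],
    merge_log: list[tuple[int, int, float]] | None = None,
) -> ClusterNode:
    """UPGMA merge tree over a distance matrix with per-leaf mutation
    totals; a single id returns its leaf.

    If ``merge_log`` is given, each merge appends
    ``(left representative, right representative, merge distance)``.
    """
    ids = dmat.ids
    if set(totals) != set(ids):
        raise ValueError("totals ids do not match distance matrix ids")
    n = len(ids)
    if n == 0:
        raise ValueError("empty distance matrix")

    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(
            total_mutations=float(totals[ids[i]]),
            sample_id=ids[i],
            _min_leaf=i,
        )
        for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    # current inter-cluster distances, keyed by (rep_i, rep_j) with i < j
    dist = {
        (i, j): float(dmat.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }

    while len(nodes) > 1:
        (i, j), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        if merge_log is not None:
            merge_log.append((i, j, d))
        left, right = nodes.pop(i), nodes.pop(j)  # left holds smaller index
        merged = ClusterNode(
            total_mutations=left.total_mutations + right.total_mutations,
            children=(left, right),
            merge_distance=d,
            similarity=1.0 - d,
            _min_leaf=i,
        )
        si, sj = sizes.pop(i), sizes.pop(j)
        for k in list(nodes):
            if k == i:
                continue
            d_ik = dist.pop((min(i, k), max(i, k)))
            d_jk = dist.pop((min(j, k), max(j, k)))
            # size-weighted mean == unweighted mean over original leaf pairs
            dist[(min(i, k), max(i, k))] = (si * d_ik + sj * d_jk) / (si + sj)
        del dist[(i, j)]
        nodes[i] = merged
        sizes[i] = si + sj

    return next(iter(nodes.values()))


@dataclass
class DoubleClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_tree: ClusterNode
    col_tree: ClusterNode


def double_cluster(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    row_totals: Mapping[str, float] | None = None,
) -> DoubleClusterResult:
    """Independently cluster the rows and the columns of a sample x
    signature matrix for heatmap ordering.

    Row totals default to row sums; column totals are the column sums
    (total mutations attributed to each signature across the cohort).
    """
    matrix = np.asarray(matrix, dtype=float)
    row_ids = list(row_ids)
    col_ids = list(col_ids)
    if matrix.shape != (len(row_ids), len(col_ids)):
        raise ValueError("matrix shape does not match row/column ids")
    if row_totals is None:
        row_totals = dict(zip(row_ids, matrix.sum(axis=1)))
    col_totals = dict(zip(col_ids, matrix.sum(axis=0)))
    row_tree = upgma(distance_matrix(matrix, row_ids), row_totals)
    col_tree = upgma(distance_matrix(matrix.T, col_ids), col_totals)
    return DoubleClusterResult(
        row_order=row_tree.leaf_order(),
        col_order=col_tree.leaf_order(),
        row_tree=row_tree,
        col_tree=col_tree,
    )


def _newick(node: ClusterNode, parent_height: float) -> str:
    length = parent_height - node.merge_distance if not node.is_leaf else parent_height
    if node.is_leaf:
        return f"{node.sample_id}:{length!r}"
    left = _newick(node.children[0], node.merge_distance)
    right = _newick(node.children[1], node.merge_distance)
    return f"({left},{right}):{length!r}"


def to_newick(tree: ClusterNode) -> str:
    """Newick serialization; node heights (merge distances) become branch
    lengths as parent height minus child height."""
    if tree.is_leaf:
        return f"{tree.sample_id}:0.0;"
    left = _newick(tree.children[0], tree.merge_distance)
    right = _newick(tree.children[1], tree.merge_distance)
    return f"({left},{right});"


def tree_to_dict(node: ClusterNode) -> dict:
    """JSON-ready nested dict with every annotation a renderer needs
    (topology only; no layout is computed)."""
    if node.is_leaf:
        return {
            "id": node.sample_id,
            "total_mutations": node.total_mutations,
        }
    return {
        "children": [tree_to_dict(c) for c in node.children],
        "merge_distance": node.merge_distance,
        "similarity": node.similarity,
        "total_mutations": node.total_mutations,
    }


def tree_from_dict(data: dict, _next_leaf: list[int] | None = None) -> ClusterNode:
    """Inverse of :func:`tree_to_dict` (leaf indexes re-assigned in leaf
    order, which reproduces the original ordering conventions)."""
    if _next_leaf is None:
        _next_leaf = [0]
    if "children" in data:
        left = tree_from_dict(data["children"][0], _next_leaf)
        right = tree_from_dict(data["children"][1], _next_leaf)
        return ClusterNode(
            total_mutations=float(data["total_mutations"]),
            children=(left, right),
            merge_distance=float(data["merge_distance"]),
            similarity=float(data["similarity"]),
            _min_leaf=min(left._min_leaf, right._min_leaf),
        )
    idx = _next_leaf[0]
    _next_leaf[0] += 1
    return ClusterNode(
        total_mutations=float(data["total_mutations"]),
        sample_id=data["id"],
        _min_leaf=idx,
    )
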