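"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the NNLS oracle is a
shrinking-box grid search over the nonnegative orthant, and the UPGMA
oracle recomputes every inter-cluster distance as the mean over all cross
pairs of *original* leaf distances at every step.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_nnls(A: np.ndarray, v: np.ndarray, rounds: int = 10, points: int = 9):
    """Grid-search solution of min ||v - A e||^2, e >= 0.

    Returns (exposures, sum of squared residuals, final per-axis step).
    The search starts from the box [0, 2||v||/||A_j||] per coordinate
    (any optimum satisfies e_j ||A_j|| <= ||A e|| <= 2||v|| for
    nonnegative A, e) and repeatedly re-grids a shrinking box around the
    best point.
    """
    A = np.asarray(A, dtype=float)
    v = np.asarray(v, dtype=float)
    k = A.shape[1]
    col_norms = np.linalg.norm(A, axis=0)
    hi = 2.0 * np.linalg.norm(v) / np.maximum(col_norms, 1e-12)
    center = hi / 2.0
    half = hi / 2.0
    best = None
    step = half  # overwritten below
    for _ in range(rounds):
        axes = [
            np.clip(np.linspace(c - h, c + h, points), 0.0, None)
            for c, h in zip(center, half)
        ]
        grid = np.array(list(itertools.product(*axes)))  # points^k x k
        resid = v[None, :] - grid @ A.T
        obj = np.einsum("ij,ij->i", resid, resid)
        best_idx = int(np.argmin(obj))
        best = (grid[best_idx].copy(), float(obj[best_idx]))
        step = 2.0 * half / (points - 1)
        center = grid[best_idx]
        half = step  # next box spans one grid step around the best point
    return best[0], best[1], step


def brute_upgma(d: np.ndarray):
    """Average-linkage merge sequence computed from first principles.

    Clusters are leaf-index sets; at each step every cross-pair mean over
    the original distance matrix is recomputed, the minimum is taken, and
    ties are broken by the lexicographically least pair of cluster
    representatives (smallest leaf index in each cluster). Returns a list
    of (left representative, right representative, merge height).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    merges: list[tuple[int, int, float]] = []
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            mean = float(
                np.mean([d[i, j] for i in ca for j in cb])
            )
            ra, rb = min(ca), min(cb)
            key = (mean, min(ra, rb), max(ra, rb))
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (a, b)
        a, b = best_pair
        merges.append((best_key[1], best_key[2], best_key[0]))
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return merges
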