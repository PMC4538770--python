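"""Cluster profiles as short Hamiltonian paths through the samples.

A cluster of p genes views the n samples as n points in p dimensions.  The
cluster's profile is an ordering of the samples along a short open
Hamiltonian path — the p-dimensional generalization of sorting: a 1-D list
is sorted exactly when the sum of absolute differences between adjacent
entries is minimal, and the path objective generalizes that sum to
Euclidean distances between adjacent sample points.

Finding the truly shortest path is the open traveling-salesman problem;
a deterministic heuristic (best of several nearest-neighbor constructions,
polished by 2-opt) is used instead, which is exact on 1-D inputs and near
optimal on the small instances that arise here.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionMatrix

__all__ = [
    "sample_distances",
    "hamiltonian_order",
    "path_length",
    "orders_equivalent",
]


def sample_distances(
    matrix: ExpressionMatrix, gene_subset: Sequence[int]
) -> np.ndarray:
    """Euclidean distances between sample columns restricted to a gene subset.

    Returns a symmetric n x n array with zero diagonal.
    """
    gene_subset = np.asarray(gene_subset, dtype=int)
    if gene_subset.size == 0:
        raise ValueError("gene_subset must be nonempty")
    if gene_subset.min() < 0 or gene_subset.max() >= matrix.n_genes:
        raise ValueError("gene_subset contains out-of-range row indices")
    points = matrix.values[gene_subset].T  # samples as points
    return squareform(pdist(points, metric="euclidean"))


def _check_distmat(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=1e-8, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return d


def path_length(distmat: np.ndarray, order: Sequence[int]) -> float:
    """Sum of distances between consecutive samples along an open path."""
    d = _check_distmat(distmat)
    n = d.shape[0]
    order = np.asarray(order, dtype=int)
    if order.shape != (n,) or not np.array_equal(np.sort(order), np.arange(n)):
        raise ValueError(f"order must be a permutation of 0..{n - 1}")
    return float(d[order[:-1], order[1:]].sum())


def _nearest_neighbor_path(d: np.ndarray, start: int) -> np.ndarray:
    # greedy construction; argmin breaks ties toward the lowest sample index
    n = d.shape[0]
    visited = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=int)
    order[0] = start
    visited[start] = True
    current = start
    for k in range(1, n):
        row = np.where(visited, np.inf, d[current])
        current = int(np.argmin(row))
        order[k] = current
        visited[current] = True
    return order


def _two_opt(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Best-improvement 2-opt descent for an open path.

    Reversing the segment order[i..j] replaces at most two edges: the one
    entering position i and the one leaving position j (none when the
    segment touches an endpoint of the path).  Iterates until no reversal
    shortens the path; never lengthens it.
    """
    order = np.array(order, dtype=int)
    n = order.size
    if n < 3:
        return order
    eps = 1e-12  # ignore float-noise "improvements" that could cycle
    while True:
        best_delta = -eps
        best_move = None
        for i in range(n - 1):
            js = np.arange(i + 1, n)
            delta = np.zeros(js.size)
            if i > 0:
                prev = order[i - 1]
                delta += d[prev, order[js]] - d[prev, order[i]]
            if js[-1] == n - 1:
                inner = js[:-1]
            else:
                inner = js
            if inner.size:
                delta[: inner.size] += (
                    d[order[i], order[inner + 1]] - d[order[inner], order[inner + 1]]
                )
            k = int(np.argmin(delta))
            if delta[k] < best_delta:
                best_delta = delta[k]
                best_move = (i, int(js[k]))
        if best_move is None:
            return order
        i, j = best_move
        order[i : j + 1] = order[i : j + 1][::-1]


def hamiltonian_order(
    distmat: np.ndarray, seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    """Heuristically shortest open path visiting every sample once.

    Builds nearest-neighbor paths from min(n, 10) seeded start points, keeps
    the shortest, and applies 2-opt until no improving segment reversal
    exists.  Deterministic given ``seed``; the result never exceeds the
    worst nearest-neighbor construction.
    """
    d = _check_distmat(distmat)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    starts = rng.choice(n, size=min(n, 10), replace=False)
    best = None
    best_len = np.inf
    for start in starts:
        order = _nearest_neighbor_path(d, int(start))
        length = float(d[order[:-1], order[1:]].sum())
        if length < best_len:
            best, best_len = order, length
    return _two_opt(d, best)


def orders_equivalent(a: Sequence[int], b: Sequence[int]) -> bool:
    """True iff two sample orders describe the same undirected path."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("orders must have equal length")
    return bool(np.array_equal(a, b) or np.array_equal(a, b[::-1]))
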