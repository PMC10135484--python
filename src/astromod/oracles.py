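"""Brute-force reference implementations used to validate the fast paths.

Each oracle recomputes a quantity by direct enumeration or a textbook
algorithm, independently of the implementation it checks: exact
permutation rank-sum p-values, O(n^3) agglomerative clustering, exhaustive
subset decomposition, and alternating nonnegative least squares for NMF.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import nnls
from scipy.stats import rankdata


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    p = P(|U - nm/2| >= |U_obs - nm/2|) over all C(n+m, n) assignments of
    the pooled (midrank-tied) values to the two groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    mu = n * m / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def agglomerative_pearson(vectors: np.ndarray, k: int,
                          linkage: str = "average") -> np.ndarray:
    """Textbook O(n^3) agglomerative clustering on 1 - Pearson distance.

    Merges the closest pair of clusters (average or complete
    inter-cluster distance over all cross pairs) until k clusters remain.
    Returns labels 0..k-1 in order of first appearance.
    """
    n = vectors.shape[0]
    corr = np.corrcoef(vectors)
    dist = 1.0 - corr
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > k:
        best = (np.inf, -1, -1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cross = [dist[a, b] for a in clusters[i] for b in clusters[j]]
                d = float(np.mean(cross)) if linkage == "average" else float(np.max(cross))
                if d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(n, dtype=int)
    next_label = 0
    seen: dict[int, int] = {}
    order = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
    for c in order:
        seen[c] = next_label
        next_label += 1
    for c, members in enumerate(clusters):
        for m in members:
            labels[m] = seen[c]
    return labels


def subset_decomposition(sets: Mapping[str, Iterable[str]]) -> dict[frozenset, int]:
    """Exhaustive count of elements per exact subset combination.

    Iterates over all 2^k - 1 non-empty subsets of set names and counts
    the elements belonging to exactly that subset.
    """
    names = list(sets)
    as_sets = {n: set(sets[n]) for n in names}
    universe = set().union(*as_sets.values()) if names else set()
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= as_sets[n]
            for n in names:
                if n not in combo:
                    inside -= as_sets[n]
            if inside:
                out[frozenset(combo)] = len(inside)
    return out


def anls_nmf_loss(X: np.ndarray, rank: int, n_restarts: int = 10,
                  n_iter: int = 60, seed: int = 0) -> float:
    """Best Frobenius loss from multi-restart alternating NNLS.

    Each restart alternates exact nonnegative least-squares solves for H
    (per column) and W (per row) from a random start; returns the lowest
    final loss across restarts.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_restarts):
        W = rng.uniform(0.1, 1.0, size=(n, rank))
        for _ in range(n_iter):
            H = np.column_stack([nnls(W, X[:, j])[0] for j in range(m)])
            W = np.column_stack([nnls(H.T, X[i, :])[0] for i in range(n)]).T
        loss = np.linalg.norm(X - W @ H)
        best = min(best, loss)
    return float(best)
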