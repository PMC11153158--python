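"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (full enumeration, O(n^2) scans) and
shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_walsh_averages(x) -> list[float]:
    x = list(map(float, x))
    out = []
    for i in range(len(x)):
        for j in range(i, len(x)):
            out.append((x[i] + x[j]) / 2.0)
    return out


def brute_pseudomedian(x) -> float:
    return float(np.median(brute_walsh_averages(x)))


def brute_wilcoxon_exact_p(x, mu=0.0) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = [xi - mu for xi in x if xi != mu]
    n = len(d)
    ranks = np.argsort(np.argsort([abs(v) for v in d])) + 1
    w_obs = sum(r for v, r in zip(d, ranks) if v > 0)
    n_total = 2 ** n
    # null: each rank positive with probability 1/2
    count = 0
    mean_w = n * (n + 1) / 4.0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / n_total


def brute_bh(pvalues) -> list[float]:
    """Definitional BH: sort, p * m / rank, running minimum from the top."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def brute_quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization with explicit tie averaging."""
    n, m = mat.shape
    reference = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat, dtype=float)
    for j in range(m):
        col = mat[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        for value in np.unique(col):
            idx = np.where(col == value)[0]
            out[idx, j] = assigned[idx].mean()
    return out


def brute_mannwhitney_exact_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p over all C(n1+n2, n1) label assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(group_idx):
        xs = [pooled[i] for i in group_idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(group_idx)]
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = 0.0
    for a in x:
        for b in y:
            u_obs += (a > b) + 0.5 * (a == b)
    mean_u = n1 * len(y) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def brute_knn_value(work: np.ndarray, i: int, j: int, k: int) -> float:
    """Expected imputed value for cell (i, j): exhaustive neighbour ranking.

    Distances are Euclidean over mutually present columns, rescaled by the
    shared-column count (sqrt(n_cols / n_shared * sum of squares)).
    """
    n, m = work.shape
    dists = []
    for r in range(n):
        if r == i or np.isnan(work[r, j]):
            continue
        shared = ~np.isnan(work[i]) & ~np.isnan(work[r])
        if not shared.any():
            continue
        sq = float(np.sum((work[i, shared] - work[r, shared]) ** 2))
        dists.append((math.sqrt(sq * m / shared.sum()), r))
    if not dists:
        return float(np.nanmean(work[i]))
    dists.sort()
    nearest = [r for _, r in dists[:k]]
    return float(np.mean([work[r, j] for r in nearest]))
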