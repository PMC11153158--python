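"""Statistical primitives shared across pipeline stages.

The Hodges–Lehmann pseudomedian and the exact/approximate one-sample
Wilcoxon signed-rank test drive the strain-wise attenuation calls; the
Benjamini–Hochberg adjustment, Mann–Whitney AUC and quantile normalization
are used by several modules.  Standard tests come from scipy/statsmodels;
only the glue and conventions (zero handling, exact-vs-approximate switch)
live here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: largest n for which the signed-rank null is evaluated exactly (no ties)
EXACT_WILCOXON_MAX_N = 25


def walsh_averages(x: np.ndarray) -> np.ndarray:
    """All pairwise means (x_i + x_j)/2 for i <= j, including i == j."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return np.empty(0)
    sums = np.add.outer(x, x)
    iu = np.triu_indices(n)
    return sums[iu] / 2.0


def pseudomedian(x: np.ndarray) -> float:
    """Hodges–Lehmann location estimate: median of the Walsh averages."""
    w = walsh_averages(x)
    if w.size == 0:
        return float("nan")
    return float(np.median(w))


def wilcoxon_onesample(x, mu: float = 0.0) -> tuple[float, float, str]:
    """Two-sided one-sample Wilcoxon signed-rank test of ``x`` against ``mu``.

    Zeros (exact ties with ``mu``) are dropped; ties among the absolute
    differences receive mid-ranks.  The exact null distribution is used for
    n <= 25 when no ties or zeros occur, otherwise the normal approximation
    with continuity correction.

    Returns ``(statistic, p_value, method)`` with method in
    {"exact", "approx", "degenerate"}.
    """
    d = np.asarray(x, dtype=float) - mu
    d = d[np.isfinite(d)]
    had_zeros = bool(np.any(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return float("nan"), 1.0, "degenerate"
    has_ties = np.unique(np.abs(d)).size < n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties and not had_zeros:
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.wilcoxon(
        d, alternative="two-sided", method="approx", correction=True
    )
    return float(res.statistic), float(res.pvalue), "approx"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs propagate unadjusted)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def mannwhitney_auc(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney test of ``x`` vs ``y`` plus the rank-based AUC.

    AUC = U / (n1 * n2) where U counts pairs with x > y (ties count 1/2);
    it estimates P(X > Y) + P(X == Y)/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    auc = float(res.statistic) / (x.size * y.size)
    return auc, float(res.pvalue)


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho with an exact permutation p-value (tiny n only)."""
    from itertools import permutations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact Spearman p is only provided for n <= 8")
    rho_obs = sps.spearmanr(x, y).statistic
    ry = sps.rankdata(y)
    count = 0
    total = 0
    rx = sps.rankdata(x)
    for perm in permutations(range(n)):
        rho = sps.spearmanr(rx, ry[list(perm)]).statistic
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return float(rho_obs), count / total


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force all columns of a complete matrix onto one shared distribution.

    Each column is replaced rank-wise by the across-column mean of the
    order statistics; tied values within a column receive the average of
    the rank-means their ranks span, so the column multisets agree up to
    tie-averaging.
    """
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n, m = arr.shape
    if n < 2:
        raise ValueError("columns need at least 2 values")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        order = np.argsort(arr[:, j], kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average rank-means over groups of tied input values
        col = pd.Series(assigned).groupby(pd.Series(arr[:, j])).transform("mean")
        out[:, j] = col.to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def ols_line(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.allclose(x, x[0]):
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def ols_through_origin(x, y) -> float:
    """No-intercept least-squares slope: sum(xy) / sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("sum(x^2) is zero")
    return float(np.dot(x, y)) / sxx
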