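"""Rank-sum testing and FDR helpers used by the classification stages.

The per-peak test is a two-sided Mann-Whitney rank-sum with mid-ranks for
ties.  P-values are exact (full enumeration of the null distribution of U,
computed once per group-size pair by dynamic programming) whenever the data
row is tie-free and min(n1, n2) <= 12; rows with ties, or larger groups,
use the tie-corrected normal approximation with continuity correction.
The exact path is vectorized as a table lookup so it is cheap to apply to
tens of thousands of peaks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_MIN_N = 12


@lru_cache(maxsize=64)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank configurations with U = u, u = 0..n1*n2 (no ties).

    Classic recurrence: adding the k-th largest of the combined sample to
    group 1 is a convolution step; counts[u] after processing all elements
    is the coefficient of q**u in the Gaussian binomial [n1+n2 choose n1]_q.
    """
    umax = n1 * n2
    c = np.zeros(umax + 1, dtype=np.float64)
    c[0] = 1.0
    # build prod_{i=1}^{n1} (1 - q^(n2+i)) / (1 - q^i), truncated at q^umax
    # (safe: kept coefficients never depend on dropped higher-order ones)
    for i in range(1, n1 + 1):
        m = n2 + i
        if m <= umax:
            c[m:] = c[m:] - c[:-m]
        for r in range(i):  # divide by (1 - q^i): strided cumulative sums
            c[r::i] = np.cumsum(c[r::i])
    return c


@lru_cache(maxsize=64)
def _u_two_sided_sf(n1: int, n2: int) -> np.ndarray:
    """table[u] = two-sided exact p for observed U1 = u (tie-free data)."""
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u)
    umax = n1 * n2
    # symmetry: P(U <= u) = P(U >= umax - u)
    p = np.empty(umax + 1)
    for u in range(umax + 1):
        p[u] = min(1.0, 2.0 * min(sf[u], sf[umax - u]))
    return p


def exact_mwu_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p for a single tie-free pair of groups."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    data = np.concatenate([x, y])
    ranks = stats.rankdata(data)
    u1 = ranks[: x.size].sum() - x.size * (x.size + 1) / 2
    return float(_u_two_sided_sf(x.size, y.size)[int(round(u1))])


def ranksum_pvalues(matrix: np.ndarray, n1: int) -> np.ndarray:
    """Two-sided rank-sum p-values for each row of ``matrix``.

    Columns ``[:n1]`` are group 1, the rest group 2.  Exact enumeration for
    tie-free rows with min group size <= 12; tie-corrected normal
    approximation (continuity-corrected) otherwise.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n_rows, n_total = matrix.shape
    n2 = n_total - n1
    ranks = stats.rankdata(matrix, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2

    srt = np.sort(matrix, axis=1)
    has_ties = (np.diff(srt, axis=1) == 0).any(axis=1)

    pvals = np.empty(n_rows)
    exact_ok = (not min(n1, n2) > EXACT_MAX_MIN_N)
    exact_rows = (~has_ties) if exact_ok else np.zeros(n_rows, bool)
    if exact_rows.any():
        table = _u_two_sided_sf(n1, n2)
        pvals[exact_rows] = table[np.rint(u1[exact_rows]).astype(int)]
    approx_rows = ~exact_rows
    if approx_rows.any():
        pvals[approx_rows] = _normal_approx_p(
            matrix[approx_rows], ranks[approx_rows], u1[approx_rows], n1, n2
        )
    return pvals


def _normal_approx_p(matrix: np.ndarray, ranks: np.ndarray, u1: np.ndarray,
                     n1: int, n2: int) -> np.ndarray:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    # tie correction: sum over tie groups of (t^3 - t), per row
    srt = np.sort(matrix, axis=1)
    tie_term = np.zeros(matrix.shape[0])
    for i in range(matrix.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    z = np.zeros_like(u1)
    nonzero = sigma > 0
    z[nonzero] = (np.abs(u1[nonzero] - mu) - 0.5) / sigma[nonzero]
    z = np.maximum(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    p[~nonzero] = 1.0  # all values tied: no evidence either way
    return np.minimum(p, 1.0)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, q >= p elementwise)."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def permutation_mean_diff_p(a: np.ndarray, b: np.ndarray, n_sims: int,
                            rng: np.random.Generator) -> float:
    """Two-sided label-permutation p for the difference of group means.

    Add-one estimator: (1 + #{|perm diff| >= |observed diff|}) / (1 + n_sims).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    pooled = np.concatenate([a, b])
    na = a.size
    obs = abs(a.mean() - b.mean())
    total = pooled.sum()
    perms = rng.permuted(np.broadcast_to(pooled, (n_sims, pooled.size)).copy(), axis=1)
    sum_a = perms[:, :na].sum(axis=1)
    diff = np.abs(sum_a / na - (total - sum_a) / b.size)
    exceed = int(np.count_nonzero(diff >= obs - 1e-12))
    return (1 + exceed) / (1 + n_sims)
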