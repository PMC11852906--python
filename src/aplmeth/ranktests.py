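"""Vectorized Wilcoxon rank tests over matrices of CpG sites.

Genome-scale differential methylation needs tens of thousands of small-sample
Wilcoxon tests per comparison; calling a scalar routine per site is the
bottleneck, so both tests are implemented here directly on (sites x samples)
arrays. Exact null distributions are used whenever they are valid (no ties
among the ranked magnitudes, and group size within ``EXACT_MAX``); otherwise a
normal approximation with tie correction and continuity correction is used —
the same policy scipy applies per call, which serves as the reference
implementation in the test suite.

Two-sided p-values from the exact distributions are computed as
``min(1, 2 * min(P(T <= t), P(T >= t)))``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX = 25  # largest group size for which exact null distributions are used
MIN_INFORMATIVE = 3  # fewer informative observations -> untestable, p = 1


# ---------------------------------------------------------------------------
# Exact null distributions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def signed_rank_cdf(n: int) -> np.ndarray:
    """CDF of the signed-rank statistic W+ under H0 for n untied pairs.

    Index w gives P(W+ <= w); W+ ranges over 0 .. n(n+1)/2. Built by the
    generating-polynomial recursion prod_i (1 + x^i) / 2^n.
    """
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for i in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[i:] = counts[:-i] if i > 0 else counts
        counts = counts + shifted
    return np.cumsum(counts) / 2.0**n


@lru_cache(maxsize=2048)
def _mwu_counts(m: int, n: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, U in 0 .. m*n."""
    if m == 0 or n == 0:
        return np.ones(1)
    a = _mwu_counts(m - 1, n)  # last first-group element ranked above all of B
    b = _mwu_counts(m, n - 1)
    out = np.zeros(m * n + 1)
    out[n : n + len(a)] += a
    out[: len(b)] += b
    return out


@lru_cache(maxsize=512)
def mann_whitney_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under H0 for untied samples.

    Index u gives P(U <= u); U ranges over 0 .. n1*n2. Counts come from the
    standard partition recurrence f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u).
    """
    counts = _mwu_counts(n1, n2)
    return np.cumsum(counts) / counts.sum()


def _two_sided_exact(cdf: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = t.astype(np.int64)
    lower = cdf[t]
    upper = 1.0 - np.where(t > 0, cdf[t - 1], 0.0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


# ---------------------------------------------------------------------------
# Shared tie bookkeeping
# ---------------------------------------------------------------------------

def _tie_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row tie correction sum(t^3 - t) and a has-ties flag.

    ``values`` may contain NaN for uninformative entries; NaNs sort last and
    never form ties. Uses the identity
    sum(t^3 - t) = 6 * (sum C(t,2) + sum C(t,3) ... ) expressed through the
    within-run position r of each element: sum r over elements = sum C(t,2),
    sum C(r,2) over elements = sum C(t,3), and t^3 - t = 6*(C(t,2) + C(t,3)).
    """
    s = np.sort(values, axis=1)  # NaN -> end of row
    n_cols = s.shape[1]
    runpos = np.zeros_like(s, dtype=np.float64)
    for j in range(1, n_cols):
        eq = s[:, j] == s[:, j - 1]
        runpos[:, j] = (runpos[:, j - 1] + 1.0) * eq
    pairs = runpos.sum(axis=1)  # sum C(t, 2)
    triples = (runpos * (runpos - 1.0) / 2.0).sum(axis=1)  # sum C(t, 3)
    tie_sum = 6.0 * (pairs + triples)
    return tie_sum, pairs > 0


# ---------------------------------------------------------------------------
# Paired signed-rank
# ---------------------------------------------------------------------------

def signed_rank_test(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon signed-rank p-values, one per row of ``diffs``.

    Zero differences (and NaNs) are dropped before ranking — Wilcoxon's
    original convention. Rows with fewer than ``MIN_INFORMATIVE`` informative
    pairs get p = 1 and are flagged untestable in the second return value.
    """
    d = np.atleast_2d(np.asarray(diffs, dtype=np.float64))
    informative = np.isfinite(d) & (d != 0.0)
    absd = np.where(informative, np.abs(d), np.nan)
    n_eff = informative.sum(axis=1)

    ranks = rankdata(absd, axis=1, nan_policy="omit")
    w_plus = np.nansum(np.where(d > 0, ranks, 0.0), axis=1)
    tie_sum, has_ties = _tie_stats(absd)

    p = np.ones(d.shape[0])
    untestable = n_eff < MIN_INFORMATIVE
    testable = ~untestable

    exact = testable & ~has_ties & (n_eff <= EXACT_MAX)
    for n in np.unique(n_eff[exact]):
        rows = exact & (n_eff == n)
        p[rows] = _two_sided_exact(signed_rank_cdf(int(n)), w_plus[rows])

    approx = testable & ~exact
    if approx.any():
        n = n_eff[approx].astype(np.float64)
        w = w_plus[approx]
        mu = n * (n + 1.0) / 4.0
        var = n * (n + 1.0) * (2.0 * n + 1.0) / 24.0 - tie_sum[approx] / 48.0
        p[approx] = _normal_two_sided(w, mu, var)
    return p, untestable


# ---------------------------------------------------------------------------
# Unpaired rank-sum (Mann-Whitney)
# ---------------------------------------------------------------------------

def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum p-values comparing rows of ``a`` against ``b``.

    NaN entries are ignored (reducing that row's effective group size). Rows
    where either group has fewer than ``MIN_INFORMATIVE`` finite values get
    p = 1 and are flagged untestable.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    n1 = a.shape[1]
    x = np.concatenate([a, b], axis=1)
    finite = np.isfinite(x)
    n1_eff = finite[:, :n1].sum(axis=1)
    n2_eff = finite[:, n1:].sum(axis=1)

    ranks = rankdata(np.where(finite, x, np.nan), axis=1, nan_policy="omit")
    r1 = np.nansum(ranks[:, :n1], axis=1)
    u1 = r1 - n1_eff * (n1_eff + 1.0) / 2.0
    tie_sum, has_ties = _tie_stats(np.where(finite, x, np.nan))

    p = np.ones(x.shape[0])
    untestable = (n1_eff < MIN_INFORMATIVE) | (n2_eff < MIN_INFORMATIVE)
    testable = ~untestable

    exact = testable & ~has_ties & (np.maximum(n1_eff, n2_eff) <= EXACT_MAX)
    for pair in {(int(i), int(j)) for i, j in zip(n1_eff[exact], n2_eff[exact])}:
        rows = exact & (n1_eff == pair[0]) & (n2_eff == pair[1])
        p[rows] = _two_sided_exact(mann_whitney_cdf(*pair), u1[rows])

    approx = testable & ~exact
    if approx.any():
        m = n1_eff[approx].astype(np.float64)
        n = n2_eff[approx].astype(np.float64)
        big_n = m + n
        mu = m * n / 2.0
        var = m * n / 12.0 * (big_n + 1.0 - tie_sum[approx] / (big_n * (big_n - 1.0)))
        p[approx] = _normal_two_sided(u1[approx], mu, var)
    return p, untestable


def _normal_two_sided(stat: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Normal-approximation p with continuity correction toward the mean."""
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    dev = stat - mu
    cc = 0.5 * np.sign(dev)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (dev - cc) / np.where(sd > 0, sd, 1.0), 0.0)
    p = np.where(sd > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    return np.minimum(p, 1.0)
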