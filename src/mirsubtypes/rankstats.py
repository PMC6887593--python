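"""Rank-based statistical primitives used throughout the pipeline.

All tests use midranks for ties.  The Kruskal-Wallis statistic is
tie-corrected; Dunn's post hoc z uses the pooled-rank variance with the
standard tie term; Mann-Whitney switches between exact enumeration (small,
tie-free inputs) and a tie-corrected normal approximation with continuity
correction; Spearman's p comes from the Student-t transform of the rank
correlation.  Benjamini-Hochberg and Bonferroni adjustments operate on raw
p-value vectors.  Distribution tail probabilities come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "OmnibusResult",
    "PairwiseTestResult",
    "MannWhitneyResult",
    "CorrelationResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "mann_whitney",
    "spearman",
    "bh_adjust",
    "bonferroni_adjust",
]


@dataclass
class OmnibusResult:
    """Tie-corrected Kruskal-Wallis result; ``p_adj`` is set by the caller."""

    H: float
    df: int
    p: float
    p_adj: float | None = None
    degenerate: bool = False


@dataclass
class PairwiseTestResult:
    group_a: str
    group_b: str
    z: float
    p: float
    p_adj: float | None = None
    direction: int = 0  # sign of mean-rank difference a - b


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    p_adj: float | None = None
    method: str = "exact"
    direction: int = 0  # sign of rank shift of a relative to b


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    p_adj: float | None = None
    valid: bool = True


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled data."""
    _, counts = np.unique(pooled, return_counts=True)
    counts = counts.astype(float)
    return float(np.sum(counts**3 - counts))


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if sum(g.size for g in gs) < 3:
        raise ValueError("need at least 3 observations in total")
    return gs


def kruskal_wallis(groups) -> OmnibusResult:
    """Kruskal-Wallis omnibus test across k groups.

    H = [12 / (N(N+1))] * sum n_i (rbar_i - (N+1)/2)^2, divided by the tie
    correction C = 1 - sum(t^3 - t) / (N^3 - N); p from the chi-square upper
    tail with k-1 degrees of freedom.  All pooled values identical gives the
    degenerate convention H = 0, p = 1.
    """
    gs = _check_groups(groups)
    k = len(gs)
    pooled = np.concatenate(gs)
    N = pooled.size
    C = 1.0 - _tie_term(pooled) / (N**3 - N)
    if C <= 0.0:
        return OmnibusResult(H=0.0, df=k - 1, p=1.0, degenerate=True)
    ranks = rankdata(pooled)
    H = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + g.size]
        start += g.size
        H += g.size * (r.mean() - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    H /= C
    return OmnibusResult(H=float(H), df=k - 1, p=float(stats.chi2.sf(H, k - 1)))


def dunn_posthoc(groups, labels=None) -> list[PairwiseTestResult]:
    """Dunn's post hoc comparisons on pooled midranks, one result per pair.

    z_ab = (rbar_a - rbar_b) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))] *
    (1/n_a + 1/n_b)); two-sided normal p; p_adj is Benjamini-Hochberg over
    the k(k-1)/2 pairs of this feature.
    """
    gs = _check_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [str(i) for i in range(k)]
    labels = list(labels)
    pooled = np.concatenate(gs)
    N = pooled.size
    tie = _tie_term(pooled)
    var_base = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    ranks = rankdata(pooled)
    means, sizes = [], []
    start = 0
    for g in gs:
        means.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    results: list[PairwiseTestResult] = []
    degenerate = var_base <= 0.0
    for a, b in itertools.combinations(range(k), 2):
        if degenerate:
            results.append(PairwiseTestResult(labels[a], labels[b], z=0.0, p=1.0, direction=0))
            continue
        diff = means[a] - means[b]
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
        results.append(
            PairwiseTestResult(
                labels[a], labels[b], z=float(z), p=float(min(p, 1.0)),
                direction=int(np.sign(diff)),
            )
        )
    adj = bh_adjust([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    return results


def _mw_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Distribution of the Mann-Whitney U statistic by exact enumeration.

    counts[u] = number of arrangements of n1 + n2 distinct values with
    U = u, via the recursion N(u; m, n) = N(u-n; m-1, n) + N(u; m, n-1).
    """
    U = n1 * n2
    f = np.zeros((n1 + 1, U + 1))
    f[:, 0] = 1.0  # n = 0: every arrangement has U = 0
    for n in range(1, n2 + 1):
        g = np.zeros_like(f)
        g[0, 0] = 1.0
        for m in range(1, n1 + 1):
            g[m] = f[m]
            g[m, n:] += g[m - 1, : U + 1 - n]
        f = g
    return f[n1]


def mann_whitney(a, b, method: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two samples.

    ``method='auto'`` uses exact enumeration when n_a * n_b <= 400 and the
    pooled data are tie-free, otherwise a normal approximation with
    tie-corrected variance and continuity correction.  ``'exact'`` /
    ``'approx'`` force a branch (exact requires tie-free data).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    N = pooled.size
    ranks = rankdata(pooled)
    U = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    ties = np.unique(pooled).size < N
    mu = na * nb / 2.0
    direction = int(np.sign(U - mu))
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and ties:
        raise ValueError("exact method requires tie-free data")
    use_exact = method == "exact" or (method == "auto" and na * nb <= 400 and not ties)
    if use_exact:
        counts = _mw_exact_counts(na, nb)
        total = counts.sum()
        u = int(round(U))
        cdf = counts[: u + 1].sum() / total
        sf = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return MannWhitneyResult(U=U, p=float(p), method="exact", direction=direction)
    tie = _tie_term(pooled)
    var = na * nb / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if var <= 0.0:
        return MannWhitneyResult(U=U, p=1.0, method="approx", direction=0)
    cc = 0.5 * np.sign(U - mu)
    z = (U - mu - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return MannWhitneyResult(U=U, p=float(p), method="approx", direction=direction)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a Student-t p-value.

    Pairs with a missing value in either vector are dropped; at least 3
    complete pairs are required.  A zero-variance rank vector yields an
    invalid result (``valid=False``) that downstream stages exclude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        return CorrelationResult(rho=float("nan"), p=1.0, n=n, valid=False)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        return CorrelationResult(rho=rho, p=0.0, n=n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = min(1.0, 2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=float(p), n=n)


def spearman_matrix(X, Y) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman correlation between the rows of X (m x n) and the
    rows of Y (k x n), with Student-t p-values.

    Vectorized form of :func:`spearman` for complete matrices (no missing
    values).  Rows with zero rank variance yield NaN rho and p = 1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the sample axis")
    n = X.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    RX = rankdata(X, axis=1)
    RY = rankdata(Y, axis=1)

    def _standardize(R):
        Rc = R - R.mean(axis=1, keepdims=True)
        norm = np.sqrt((Rc**2).sum(axis=1, keepdims=True))
        bad = norm[:, 0] <= 0
        norm[bad] = 1.0
        Z = Rc / norm
        Z[bad] = np.nan
        return Z

    rho = np.clip(_standardize(RX) @ _standardize(RY).T, -1.0, 1.0)
    p = np.ones_like(rho)
    finite = np.isfinite(rho)
    interior = finite & (np.abs(rho) < 1.0)
    t = np.zeros_like(rho)
    t[interior] = rho[interior] * np.sqrt((n - 2) / (1.0 - rho[interior] ** 2))
    p[interior] = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t[interior]), n - 2))
    p[finite & (np.abs(rho) >= 1.0)] = 0.0
    return rho, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(p * m, 1); m defaults to the vector length."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(p * m, 1.0)
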