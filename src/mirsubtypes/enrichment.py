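"""Per-sample gene-set enrichment scores via a kernel-CDF rank statistic.

The method follows the gene set variation analysis family: each gene's
expression across samples is turned into a smoothed empirical CDF value with
a Gaussian kernel (bandwidth s_i / 4), genes are ranked per sample by
decreasing CDF value, positions get the symmetric weight |p/2 - d|, and a
weighted Kolmogorov-like walk over the ranked genes yields one enrichment
score per set per sample, in [-1, 1].

Two score conventions are supported: ``max_diff`` (largest positive plus
largest negative deviation of the walk) and ``max_abs`` (deviation of
maximal magnitude, signed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from mirsubtypes.io_formats import ExprMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentScores:
    """Gene-set x sample enrichment score matrix with the convention used."""

    scores: pd.DataFrame
    convention: str = "max_diff"
    tau: float = 1.0
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def kernel_cdf(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel smoothed empirical CDF per gene.

    z_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i) with h_i = s_i / 4 (sample
    standard deviation).  Zero-variance genes get the degenerate-safe
    constant 1/2.  Requires at least 3 samples.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    p, n = X.shape
    if n < 3:
        raise ValueError(f"kernel CDF needs at least 3 samples, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("kernel CDF requires a complete matrix")
    sd = X.std(axis=1, ddof=1)
    out = np.empty_like(X)
    zero = sd <= 0.0
    out[zero] = 0.5
    live = np.flatnonzero(~zero)
    # chunk genes to bound the p x n x n intermediate
    chunk = max(1, int(4_000_000 / max(n * n, 1)))
    for start in range(0, live.size, chunk):
        idx = live[start : start + chunk]
        d = (X[idx, :, None] - X[idx, None, :]) / sd[idx, None, None] * 4.0
        out[idx] = ndtr(d).mean(axis=2)
    return out


def rank_statistic(zhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample gene ordering by decreasing kernel-CDF value plus the
    symmetric positional weights.

    Returns ``order`` (p x n; ``order[l, j]`` is the gene index at position
    l+1 in sample j) and the weight vector ``w`` with w[l] = |p/2 - (l+1)|.
    Ties are broken by stable input gene order (logged).
    """
    Z = np.asarray(zhat, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("rank statistic requires finite values")
    p, n = Z.shape
    order = np.argsort(-Z, axis=0, kind="stable")
    n_ties = sum(np.unique(Z[:, j]).size < p for j in range(n))
    if n_ties:
        logger.debug("rank_statistic: %d samples contain tied CDF values", n_ties)
    positions = np.arange(1, p + 1, dtype=float)
    w = np.abs(p / 2.0 - positions)
    return order, w


def walk_es(
    order: np.ndarray,
    weights: np.ndarray,
    member_mask: np.ndarray,
    tau: float = 1.0,
    convention: str = "max_diff",
) -> np.ndarray:
    """Weighted random-walk enrichment score for one gene set, per sample.

    nu(l) = sum_{i<=l, g_i in S} w_i^tau / sum_{i in S} w_i^tau
          - sum_{i<=l, g_i not in S} 1 / (p - |S|)
    ``max_diff``: ES = max(nu)^+ + min(nu)^-; ``max_abs``: signed deviation of
    maximal magnitude.
    """
    p, n = order.shape
    member_mask = np.asarray(member_mask, dtype=bool)
    n_set = int(member_mask.sum())
    if n_set == 0:
        raise ValueError("gene set has no measured members")
    if n_set >= p:
        raise ValueError("gene set covers all measured genes (walk undefined)")
    ind = member_mask[order]  # p x n, membership in ranked position space
    rw = np.power(weights, tau)[:, None] * ind
    denom = rw.sum(axis=0)
    if np.any(denom <= 0.0):
        # all member weights zero can only happen for pathological tiny p
        denom = np.where(denom <= 0.0, 1.0, denom)
    inc = np.cumsum(rw, axis=0) / denom
    dec = np.cumsum(~ind, axis=0) / float(p - n_set)
    nu = inc - dec
    if convention == "max_diff":
        return nu.max(axis=0).clip(min=0.0) + nu.min(axis=0).clip(max=0.0)
    if convention == "max_abs":
        idx = np.abs(nu).argmax(axis=0)
        return nu[idx, np.arange(n)]
    raise ValueError(f"unknown convention {convention!r}")


def score_sets(
    m: ExprMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    convention: str = "max_diff",
    min_size: int = 2,
) -> EnrichmentScores:
    """Kernel CDF -> rank statistic -> walk, for every retained gene set.

    Sets with fewer than ``min_size`` measured genes are skipped with a
    logged reason; a set covering every measured gene is an error.
    """
    zhat = kernel_cdf(m.values.to_numpy(dtype=float))
    order, w = rank_statistic(zhat)
    feature_index = {g: i for i, g in enumerate(m.feature_ids)}
    p = len(feature_index)
    rows, names, skipped = [], [], {}
    for name in sets.names:
        members = sets.members(name)
        mask = np.zeros(p, dtype=bool)
        for g in members:
            i = feature_index.get(g)
            if i is not None:
                mask[i] = True
        k = int(mask.sum())
        if k < min_size:
            skipped[name] = f"only {k} measured genes (min_size={min_size})"
            logger.info("skipping gene set %s: %s", name, skipped[name])
            continue
        rows.append(walk_es(order, w, mask, tau=tau, convention=convention))
        names.append(name)
    data = np.asarray(rows) if rows else np.zeros((0, len(m.sample_ids)))
    scores = pd.DataFrame(data, index=names, columns=m.sample_ids)
    return EnrichmentScores(scores=scores, convention=convention, tau=tau, skipped=skipped)
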