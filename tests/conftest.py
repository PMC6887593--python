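"""Shared fixtures: a derandomized hypothesis profile, small study
configurations, and the independent brute-force enrichment oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _enrichment_oracle(X, memberships, tau=1.0, convention="max_diff"):
    """Direct double-summation implementation of the kernel-CDF / rank-weight /
    walk formulas, independent of the package's vectorized path.

    ``memberships`` maps set name -> iterable of gene row indices.  Returns
    (zhat, {set_name: ES per sample}).
    """
    X = np.asarray(X, dtype=float)
    p, n = X.shape
    z = np.zeros((p, n))
    for i in range(p):
        s = float(np.std(X[i], ddof=1))
        if s <= 0.0:
            z[i, :] = 0.5
            continue
        h = s / 4.0
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += 0.5 * (1.0 + math.erf((X[i, j] - X[i, k]) / (h * math.sqrt(2.0))))
            z[i, j] = acc / n
    es = {}
    for name, members in memberships.items():
        members = set(int(g) for g in members)
        n_set = len(members & set(range(p)))
        vals = np.zeros(n)
        for j in range(n):
            order = sorted(range(p), key=lambda g: -z[g, j])  # stable: ties by index
            den = sum(
                abs(p / 2.0 - (pos + 1)) ** tau
                for pos, g in enumerate(order)
                if g in members
            )
            if den <= 0.0:
                den = 1.0
            num = 0.0
            n_out = 0
            best_pos = best_neg = best_signed = 0.0
            for pos, g in enumerate(order):
                if g in members:
                    num += abs(p / 2.0 - (pos + 1)) ** tau
                else:
                    n_out += 1
                # divide accumulated sums once, so magnitude ties between
                # +x and -x resolve identically to the vectorized path
                v = num / den - n_out / (p - n_set)
                best_pos = max(best_pos, v)
                best_neg = min(best_neg, v)
                if abs(v) > abs(best_signed):
                    best_signed = v
            vals[j] = best_pos + best_neg if convention == "max_diff" else best_signed
        es[name] = vals
    return z, es


@pytest.fixture(scope="session")
def enrichment_oracle():
    return _enrichment_oracle


@pytest.fixture
def small_sim_config():
    """A fast study configuration preserving the default structure."""
    from mirsubtypes.synthetic_cohort import SimConfig

    return SimConfig(
        seed=0,
        n_discovery=150,
        n_validation=200,
        n_normal_validation=20,
        n_mirnas=60,
        n_genes=220,
        n_classifier_genes=60,
        n_gene_sets=12,
        set_size=12,
        n_markers=6,
        n_targets=6,
    )
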