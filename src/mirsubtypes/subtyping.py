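"""Nearest-centroid expression subtyping by Pearson correlation.

Each tumor sample is correlated with every subtype centroid over the
classifier genes present in the data; the sample is assigned the
most-correlated subtype, or left UNASSIGNED when it correlates negatively
with all centroids.  Genes are median-centered across the cohort's tumor
samples before correlation (the published centroid classifiers were trained
on centered data); the flag is exposed because real inputs may already be
centered.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from mirsubtypes.io_formats import UNASSIGNED, CentroidModel, ExprMatrix

logger = logging.getLogger(__name__)


def classify(
    m: ExprMatrix,
    model: CentroidModel,
    tumor_samples: list[str] | None = None,
    center_genes: bool | None = None,
) -> pd.DataFrame:
    """Assign an expression subtype to each tumor sample.

    Returns a DataFrame indexed by sample id with one correlation column per
    subtype (``corr_<name>``), the assignment, and the number of classifier
    genes used.  Ties at the maximum are broken by subtype-name order with a
    logged warning.  Normal samples are excluded by passing ``tumor_samples``.
    """
    if center_genes is None:
        center_genes = model.center_genes
    samples = list(m.sample_ids) if tumor_samples is None else list(tumor_samples)
    genes = [g for g in model.classifier_genes if g in set(m.feature_ids)]
    if len(genes) < 2:
        raise ValueError(
            f"only {len(genes)} classifier genes overlap the matrix; need at least 2"
        )
    frac = len(genes) / len(model.classifier_genes)
    suppress_all = frac < 0.5
    if suppress_all:
        logger.warning(
            "only %.0f%% of classifier genes present (<50%%); all calls suppressed", 100 * frac
        )

    X = m.values.loc[genes, samples].to_numpy(dtype=float)
    C = model.values.loc[genes].to_numpy(dtype=float)
    subtypes = model.subtype_names
    if center_genes:
        med = np.nanmedian(X, axis=1, keepdims=True)
        Xc = X - med
    else:
        Xc = X

    records = []
    fallback_samples: list[str] = []
    for j, sample in enumerate(samples):
        profile = Xc[:, j]
        raw = X[:, j]
        used = np.isfinite(profile)
        n_used = int(used.sum())
        if n_used < 2 or suppress_all:
            records.append(_record(sample, subtypes, [np.nan] * len(subtypes), UNASSIGNED, n_used))
            continue
        prof = profile[used]
        if np.ptp(prof) == 0.0:
            # Median centering can collapse a whole sample to a constant when
            # one subtype dominates the cohort; fall back to the uncentered
            # profile, which still carries the sample's pattern.
            if np.ptp(raw[used]) == 0.0:
                logger.warning("sample %s has a constant profile; UNASSIGNED", sample)
                records.append(
                    _record(sample, subtypes, [np.nan] * len(subtypes), UNASSIGNED, n_used)
                )
                continue
            fallback_samples.append(sample)
            prof = raw[used]
        cors = []
        for k in range(len(subtypes)):
            cent = C[used, k]
            if np.ptp(cent) == 0.0:
                cors.append(np.nan)
            else:
                cors.append(float(np.corrcoef(prof, cent)[0, 1]))
        cors_arr = np.asarray(cors)
        finite = np.isfinite(cors_arr)
        if not finite.any() or np.nanmax(cors_arr) <= 0.0:
            assigned = UNASSIGNED
        else:
            best = np.nanmax(cors_arr)
            tied = [k for k in range(len(subtypes)) if finite[k] and cors_arr[k] == best]
            if len(tied) > 1:
                logger.warning("sample %s ties between %s; using name order", sample,
                               [subtypes[k] for k in tied])
                tied.sort(key=lambda k: subtypes[k])
            assigned = subtypes[tied[0]]
        records.append(_record(sample, subtypes, cors, assigned, n_used))
    if fallback_samples:
        logger.warning(
            "%d samples collapsed to a constant after median centering "
            "(dominant-subtype degeneracy); classified on uncentered profiles: %s%s",
            len(fallback_samples), fallback_samples[:3],
            "..." if len(fallback_samples) > 3 else "",
        )
    df = pd.DataFrame(records).set_index("sample_id")
    return df


def _record(sample, subtypes, cors, assigned, n_used) -> dict:
    rec = {"sample_id": sample}
    for name, c in zip(subtypes, cors):
        rec[f"corr_{name}"] = c
    rec["assigned"] = assigned
    rec["n_genes_used"] = n_used
    return rec


def accuracy(calls: pd.DataFrame, truth: pd.Series) -> float:
    """Fraction of samples assigned their true subtype (over truth's samples)."""
    common = [s for s in truth.index if s in calls.index]
    if not common:
        raise ValueError("no overlapping samples between calls and truth")
    hits = sum(calls.loc[s, "assigned"] == truth[s] for s in common)
    return hits / len(common)
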