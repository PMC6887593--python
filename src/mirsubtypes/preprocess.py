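"""Normalization and detection filtering of expression matrices.

miRNA arrays are normalized by subtracting each sample's 90th percentile on
the log2 scale (equivalent to division on the raw scale); mRNA data are
quantile normalized so every sample shares one empirical distribution.
Features detected in fewer than a branch-specific fraction of samples are
removed (strictly-below rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mirsubtypes.io_formats import ExprMatrix

logger = logging.getLogger(__name__)


@dataclass
class DetectionFilterReport:
    kept: list[str]
    removed: list[str]
    fractions: pd.Series  # detection fraction per input feature

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.fractions.index,
                "detection_fraction": self.fractions.to_numpy(),
                "kept": [f in set(self.kept) for f in self.fractions.index],
            }
        )


def log2_transform(m: ExprMatrix, already_log: bool = False) -> ExprMatrix:
    """Replace values by log2(value); ``already_log`` short-circuits to identity."""
    if already_log:
        return m
    vals = m.values
    bad = (vals <= 0).to_numpy() & np.isfinite(vals.to_numpy())
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value at feature {vals.index[i]!r}, sample {vals.columns[j]!r}"
        )
    out = np.log2(vals)
    return ExprMatrix(out, m.detected.copy() if m.detected is not None else None)


def percentile_normalize(m: ExprMatrix, q: float = 90.0) -> ExprMatrix:
    """Subtract each sample's q-th percentile (linear-interpolation definition,
    non-missing values only) so that percentile becomes 0."""
    vals = m.values
    out = vals.copy()
    for col in vals.columns:
        v = vals[col].to_numpy(dtype=float)
        finite = np.isfinite(v)
        if not finite.any():
            raise ValueError(f"sample {col!r} has no non-missing values")
        out[col] = v - np.percentile(v[finite], q)
    return ExprMatrix(out, m.detected.copy() if m.detected is not None else None)


def quantile_normalize(m: ExprMatrix) -> ExprMatrix:
    """Map each sample onto the across-sample mean of order statistics.

    Ties within a sample receive the mean of the reference values at their
    tied ranks, so the result does not depend on input order.  Missing values
    are not supported and must be handled upstream.
    """
    vals = m.values
    X = vals.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("quantile_normalize requires a complete matrix; impute or drop missing values upstream")
    p, n = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n):
        order = np.argsort(X[:, j], kind="stable")
        sortedv = X[order, j]
        mapped = ref.copy()
        # average reference values over tie groups
        start = 0
        while start < p:
            stop = start + 1
            while stop < p and sortedv[stop] == sortedv[start]:
                stop += 1
            if stop - start > 1:
                mapped[start:stop] = ref[start:stop].mean()
            start = stop
        out[order, j] = mapped
    df = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return ExprMatrix(df, m.detected.copy() if m.detected is not None else None)


def detection_filter(
    m: ExprMatrix, min_fraction: float
) -> tuple[ExprMatrix, DetectionFilterReport]:
    """Remove features detected in strictly fewer than ``min_fraction`` of samples.

    Detection comes from the matrix's ``detected`` flags; without flags, a
    non-missing value counts as detected.
    """
    if m.detected is not None:
        det = m.detected.to_numpy(dtype=bool)
    else:
        det = np.isfinite(m.values.to_numpy(dtype=float))
    frac = det.mean(axis=1)
    keep_mask = frac >= min_fraction
    features = list(m.values.index)
    kept = [f for f, k in zip(features, keep_mask) if k]
    removed = [f for f, k in zip(features, keep_mask) if not k]
    report = DetectionFilterReport(
        kept=kept, removed=removed, fractions=pd.Series(frac, index=features)
    )
    if removed:
        logger.info("detection filter removed %d/%d features", len(removed), len(features))
    return m.subset_features(kept), report
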