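"""Pre-correction processing: log2 transform, presence filtering, imputation.

Targeted and untargeted LC-MS intensity tables are log2-transformed per
feature before any statistical correction; missingness in MS data is
predominantly left-censored (below the limit of detection), so the default
imputation is the half-minimum rule. A correlation-based kNN imputation is
available for data where missingness is not detection-limited.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import LOG2, FeatureMatrix, FeatureTableError, RAW

logger = logging.getLogger("debatch")


def log2_transform(fm: FeatureMatrix, offset: float = 0.0) -> FeatureMatrix:
    """Replace each finite intensity y by log2(y + offset).

    Missing entries stay missing; ``scale_flag`` becomes ``"log2"``.
    Raises if the table is already on the log2 scale or if any finite
    ``y + offset`` is non-positive (the offending sample/feature is named).
    """
    if fm.scale_flag != RAW:
        raise FeatureTableError("log2_transform expects raw-scale intensities")
    if offset < 0:
        raise FeatureTableError("offset must be non-negative")
    shifted = fm.intensities + offset
    bad = (shifted <= 0) & fm.intensities.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FeatureTableError(
            f"log2 undefined: intensity + offset <= 0 at sample "
            f"{fm.sample_ids[r]!r}, feature {fm.feature_ids[c]!r}"
        )
    out = fm.with_intensities(np.log2(shifted))
    out.scale_flag = LOG2
    return out


def filter_features(fm: FeatureMatrix, min_presence: float = 0.8) -> FeatureMatrix:
    """Keep features observed in >= ``min_presence`` of non-QC samples."""
    if not 0 <= min_presence <= 1:
        raise FeatureTableError("min_presence must lie in [0, 1]")
    study = fm.intensities.loc[~fm.is_qc]
    presence = study.notna().mean(axis=0)
    keep = presence[presence >= min_presence].index
    removed = [f for f in fm.feature_ids if f not in set(keep)]
    if removed:
        logger.info(
            "filter_features removed %d/%d features below presence %.2f: %s",
            len(removed), fm.n_features, min_presence, removed[:10],
        )
    return fm.subset_features(list(keep))


def impute_missing(
    fm: FeatureMatrix, method: str = "half_min", k: int = 5
) -> FeatureMatrix:
    """Fill missing entries; observed entries are never modified.

    ``half_min`` replaces a feature's missing values by half its minimum
    observed value on the current scale (the classic below-LOD
    convention).  ``knn``
    replaces them by the mean of the ``k`` most correlated features,
    computed across samples where both are observed.
    """
    values = fm.intensities.copy()
    fully_missing = values.columns[values.isna().all(axis=0)]
    if len(fully_missing):
        raise FeatureTableError(
            f"feature(s) with no observed value: {list(fully_missing)}; "
            "run filter_features first"
        )
    if not values.isna().any().any():
        return fm.copy()

    if method == "half_min":
        values = values.fillna(values.min(axis=0) / 2.0)
    elif method == "knn":
        if k < 1:
            raise FeatureTableError("k must be a positive integer")
        corr = values.corr(min_periods=3).abs()
        np.fill_diagonal(corr.values, np.nan)
        col_means = values.mean(axis=0)
        for g in values.columns[values.isna().any(axis=0)]:
            neighbors = corr[g].dropna().nlargest(k).index
            if len(neighbors) == 0:
                values[g] = values[g].fillna(col_means[g])
                continue
            donor = values[neighbors].mean(axis=1)
            values[g] = values[g].fillna(donor).fillna(col_means[g])
    else:
        raise FeatureTableError(f"unknown imputation method {method!r}")
    return fm.with_intensities(values)
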