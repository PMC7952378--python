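"""QC-sample-based lowess signal-drift correction.

The reference comparator for the statistical models: for each feature a
locally weighted regression of the QC intensities on injection order
traces the instrument drift, and every sample is rescaled by the ratio of
the feature's reference level (the median QC intensity) to the drift
curve evaluated at its injection order.  On the log2 scale the ratio
becomes a subtraction of the fitted-minus-reference difference.

Because the drift curve exists only where QCs were measured, features
absent from the QC injections cannot be corrected and are dropped — the
structural limitation of every QC-based method (low-abundance analytes
diluted below detection in pooled QCs are lost).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .data_model import LOG2, CorrectionResult, FeatureMatrix
from .correction_ls import CorrectionError

logger = logging.getLogger("debatch")

MIN_QC_PER_WINDOW = 3


def _fit_drift(
    qc_order: np.ndarray, qc_values: np.ndarray, eval_order: np.ndarray, frac: float
) -> np.ndarray:
    """Lowess fit of QC intensity on order, evaluated at ``eval_order``.

    Tricube-weighted local linear fit with 2 robustness iterations;
    between QC injections the curve is linearly interpolated, beyond the
    first/last QC it is held constant (linear extrapolation can blow up
    at the ends of a run).
    """
    fitted = sm_lowess(
        qc_values, qc_order, frac=frac, it=2, return_sorted=True
    )
    return np.interp(eval_order, fitted[:, 0], fitted[:, 1])


def lowess_correct(
    fm: FeatureMatrix,
    frac: float = 0.5,
    per_batch: bool = True,
    **_ignored,
) -> CorrectionResult:
    """Correct within-run signal drift using the QC injections.

    Parameters
    ----------
    frac
        Lowess span: fraction of QC points entering each local fit.
    per_batch
        Fit one drift curve per batch (default) instead of one curve over
        the whole acquisition order.

    Features with fewer than 3 non-missing QC measurements in any fitting
    window, or whose fitted drift level is non-positive on the raw scale,
    are dropped and listed in ``dropped_features``.
    """
    if not 0 < frac <= 1:
        raise CorrectionError("frac must lie in (0, 1]")
    n_qc = int(fm.is_qc.sum())
    if n_qc == 0:
        raise CorrectionError(
            "no QC samples in the dataset: QC-based correction is impossible; "
            "use one of the statistical models (ber, combat_*) instead"
        )

    windows: list[pd.Series] = (
        [(fm.batch == b) for b in fm.batches] if per_batch
        else [pd.Series(True, index=fm.sample_ids)]
    )
    log_scale = fm.scale_flag == LOG2
    corrected = fm.intensities.copy()
    dropped: list[tuple[str, str]] = []

    for feature in fm.feature_ids:
        y = fm.intensities[feature]
        qc_observed = y[fm.is_qc].dropna()
        reference = float(qc_observed.median()) if len(qc_observed) else np.nan
        fitted_all = pd.Series(np.nan, index=fm.sample_ids)
        reason = None
        for window in windows:
            qc_mask = window & fm.is_qc & y.notna()
            if int(qc_mask.sum()) < MIN_QC_PER_WINDOW:
                reason = (
                    f"fewer than {MIN_QC_PER_WINDOW} QC measurements in a "
                    "fitting window"
                )
                break
            fitted = _fit_drift(
                fm.injection_order[qc_mask].to_numpy(float),
                y[qc_mask].to_numpy(float),
                fm.injection_order[window].to_numpy(float),
                frac,
            )
            if not log_scale and np.any(fitted <= 0):
                reason = "non-positive fitted drift level"
                break
            fitted_all[window.to_numpy()] = fitted
        if reason is not None:
            dropped.append((feature, reason))
            continue
        if log_scale:
            corrected[feature] = y - (fitted_all - reference)
        else:
            corrected[feature] = y * (reference / fitted_all)

    kept = [f for f in fm.feature_ids if f not in {d[0] for d in dropped}]
    out = fm.subset_features(kept)
    out.intensities = corrected[kept]
    result = CorrectionResult(
        corrected=out, model_name="qc_lowess",
        internals={"frac": frac, "per_batch": per_batch, "n_qc": n_qc},
        dropped_features=dropped,
    )
    for feature, why in dropped:
        result.log("warning", "LOWESS_DROP", f"dropped {feature!r}: {why}")
    result.log(
        "info", "LOWESS_FIT",
        f"corrected {len(kept)}/{fm.n_features} features with {n_qc} QCs",
    )
    return result
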