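"""Post-correction validation statistics.

Three analyses used to check that a correction recovers biology rather
than merely flattening batches: a Pearson correlation with a Fisher-z
confidence interval (e.g. MS-measured vs clinically measured creatinine),
a covariate-adjusted per-feature association scan against a continuous
outcome (e.g. estimated GFR adjusted for age and sex, Bonferroni
controlled), and a two-group differential analysis with
Benjamini-Hochberg FDR control and a fold-change cutoff, per-feature
ordinary least squares standing in for moderated statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import FeatureMatrix

logger = logging.getLogger("debatch")


class AnalysisError(ValueError):
    """Raised for downstream-analysis precondition failures."""


@dataclass
class FisherCorrelation:
    """Pearson r with its Fisher-z transform and CI (both scales)."""

    r: float
    z: float
    ci_low: float
    ci_high: float
    r_ci_low: float
    r_ci_high: float
    n: int


def pearson_fisher(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> FisherCorrelation:
    """Pearson correlation with a Fisher-z confidence interval.

    z = atanh(r) is approximately normal with standard error
    1/sqrt(n - 3); the CI is reported on the z scale and back-transformed
    to the r scale with tanh.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise AnalysisError("need at least 4 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AnalysisError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("zero-variance input: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    z = float(np.arctanh(r))
    half_width = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    lo, hi = z - half_width, z + half_width
    return FisherCorrelation(
        r=r, z=z, ci_low=lo, ci_high=hi,
        r_ci_low=float(np.tanh(lo)), r_ci_high=float(np.tanh(hi)), n=n,
    )


def association_scan(
    fm: FeatureMatrix,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature multiple regression of an outcome on each metabolite.

    For every feature, fits ``outcome ~ metabolite + covariates`` by
    least squares on the samples where outcome (and covariates) are
    available — subset selection is implicit, mirroring cohorts where
    clinical metadata cover only part of the samples.  Reports the
    metabolite coefficient, its two-sided p-value, and the Bonferroni
    adjusted p (multiplied by the number of features tested, capped at 1).
    A collinear design fails only that feature; the scan continues.
    """
    study_ids = fm.sample_ids[~fm.is_qc]
    outcome = outcome.reindex(study_ids)
    keep = outcome.notna()
    if covariates is not None:
        covariates = covariates.reindex(study_ids)
        keep &= covariates.notna().all(axis=1)
    ids = study_ids[keep]
    if len(ids) < 3:
        raise AnalysisError("fewer than 3 samples with complete outcome/covariates")
    yv = outcome[ids].to_numpy(float)
    C = None if covariates is None else covariates.loc[ids].to_numpy(float)

    rows = []
    for feature in fm.feature_ids:
        x = fm.intensities.loc[ids, feature].to_numpy(float)
        ok = np.isfinite(x)
        X_cols = [np.ones(ok.sum()), x[ok]]
        if C is not None:
            X_cols.extend(C[ok].T)
        X = np.column_stack(X_cols)
        y_ok = yv[ok]
        df_resid = X.shape[0] - X.shape[1]
        if df_resid < 1 or np.linalg.matrix_rank(X) < X.shape[1]:
            logger.warning("association_scan: singular design for %r; skipped", feature)
            rows.append(
                {"feature": feature, "coefficient": np.nan, "p": np.nan, "n": int(ok.sum())}
            )
            continue
        coef, _, _, _ = np.linalg.lstsq(X, y_ok, rcond=None)
        resid = y_ok - X @ coef
        sigma2 = resid @ resid / df_resid
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t_stat = coef[1] / np.sqrt(cov[1, 1])
        p = 2 * stats.t.sf(abs(t_stat), df_resid)
        rows.append(
            {"feature": feature, "coefficient": float(coef[1]), "p": float(p), "n": int(ok.sum())}
        )
    table = pd.DataFrame(rows).set_index("feature")
    m = fm.n_features
    table["p_bonferroni"] = np.minimum(table["p"] * m, 1.0)
    return table


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def differential_analysis(
    fm: FeatureMatrix,
    group: pd.Series,
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential analysis on log2-scale intensities.

    Per feature: log2FC = mean(group2) - mean(group1); a two-sided
    per-feature linear-model (equal-variance t) p-value; BH step-up
    adjustment across features.  A feature is significant iff
    |log2FC| > ``lfc_threshold`` and BH-adjusted p < ``alpha``.  The
    returned table is volcano-ready (log2FC vs -log10 adjusted p).
    """
    study_ids = fm.sample_ids[~fm.is_qc]
    group = group.reindex(study_ids).dropna()
    levels = sorted(pd.unique(group))
    if len(levels) != 2:
        raise AnalysisError(f"need exactly 2 groups, found {levels}")
    ids1 = group.index[group == levels[0]]
    ids2 = group.index[group == levels[1]]
    if len(ids1) < 2 or len(ids2) < 2:
        raise AnalysisError("each group needs at least 2 samples")

    a = fm.intensities.loc[ids1].to_numpy(float)
    b = fm.intensities.loc[ids2].to_numpy(float)
    log2fc = np.nanmean(b, axis=0) - np.nanmean(a, axis=0)
    t_res = stats.ttest_ind(b, a, equal_var=True, nan_policy="omit")
    p = np.asarray(t_res.pvalue, float)
    p_bh = benjamini_hochberg(np.where(np.isfinite(p), p, 1.0))
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p": p,
            "p_bh": p_bh,
            "neg_log10_p_bh": -np.log10(np.maximum(p_bh, np.finfo(float).tiny)),
        },
        index=pd.Index(fm.feature_ids, name="feature"),
    )
    table["significant"] = (np.abs(table["log2FC"]) > lfc_threshold) & (
        table["p_bh"] < alpha
    )
    table.attrs["groups"] = {"group1": levels[0], "group2": levels[1]}
    return table
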