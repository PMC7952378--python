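"""Model-selection scoring and dataset diagnostics.

The selection score asks, feature by feature, how much of a feature's
variance is explained by batch membership: a one-way least-squares fit of
intensity on batch indicators gives R^2 = SS_between / SS_total, penalized
for degrees of freedom as

    adj-R^2 = 1 - (1 - R^2) (n - 1) / (n - B)

with n samples and B batches.  A model's score is the maximum adj-R^2
over features, clipped below at zero for reporting (a near-zero or
negative maximum means no feature retains detectable batch dependence —
the mark of a successful correction; the lower the score, the better the
model).  The unclipped maximum is kept alongside, since strongly negative
values are themselves informative: they indicate a regression with
essentially no batch signal to fit.

Diagnostics mirror standard metabolomics QA: PCA score plots and
hierarchical clustering at the sample level, kernel-density and
violin/box summaries per feature at the feature level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .data_model import FeatureMatrix

logger = logging.getLogger("debatch")


class ScoringError(ValueError):
    """Raised for scoring/diagnostic preconditions."""


# ---------------------------------------------------------------------------
# batch-dependence score
# ---------------------------------------------------------------------------

def batch_adj_r2(fm: FeatureMatrix) -> pd.Series:
    """Per-feature adjusted R^2 of intensity regressed on batch.

    QC samples are excluded; missing entries are dropped pairwise with a
    per-feature n.  A zero-total-variance feature is reported as 0 with a
    warning (no variance to explain).  Raises when a feature has no
    residual degrees of freedom (n <= B).
    """
    study = fm.intensities.loc[~fm.is_qc]
    batch = fm.batch[~fm.is_qc]
    n_batches_total = len(fm.batches)
    if n_batches_total < 2:
        raise ScoringError("batch_adj_r2 needs at least 2 batches")
    out = {}
    values = study.to_numpy(float)
    batch_codes = pd.Categorical(batch).codes
    for j, feature in enumerate(study.columns):
        y = values[:, j]
        ok = ~np.isnan(y)
        yv, bv = y[ok], batch_codes[ok]
        n = yv.size
        B = np.unique(bv).size
        if B < 2 or n <= B:
            raise ScoringError(
                f"feature {feature!r}: n={n} observed values over B={B} batches "
                "leaves no residual degrees of freedom"
            )
        ss_total = ((yv - yv.mean()) ** 2).sum()
        if ss_total <= 0:
            logger.warning(
                "feature %r has zero total variance; adj-R^2 reported as 0", feature
            )
            out[feature] = 0.0
            continue
        ss_between = sum(
            (yv[bv == code].size) * (yv[bv == code].mean() - yv.mean()) ** 2
            for code in np.unique(bv)
        )
        r2 = ss_between / ss_total
        out[feature] = 1.0 - (1.0 - r2) * (n - 1) / (n - B)
    return pd.Series(out, name="adj_r2")


@dataclass
class ScoreReport:
    """Per-feature batch adj-R^2 for one corrected dataset plus its summary.

    ``score`` is max over features clipped to [0, 1]; ``raw_max`` the
    unclipped maximum (may be negative after an effective correction);
    ``mean_adj_r2`` the consistency summary used to break ranking ties.
    """

    model_name: str
    adj_r2: pd.Series
    n_samples: int
    n_batches: int
    score: float = field(init=False)
    raw_max: float = field(init=False)
    mean_adj_r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.raw_max, self.score = model_score(self.adj_r2)
        self.mean_adj_r2 = float(self.adj_r2.mean())


def model_score(adj_r2: pd.Series | np.ndarray) -> tuple[float, float]:
    """(raw maximum, reported score) of an adj-R^2 vector.

    The reported score is the maximum over features clipped below at 0 —
    so it lives in [0, 1] — while the raw maximum is preserved because
    negative maxima carry information about over-fit-free corrections.
    """
    arr = np.asarray(adj_r2, float)
    if arr.size == 0:
        raise ScoringError("empty adj-R^2 vector")
    raw = float(np.max(arr))
    return raw, float(min(max(raw, 0.0), 1.0))


def score_models(
    datasets: dict[str, FeatureMatrix]
) -> dict[str, ScoreReport]:
    """Score a set of (model name -> corrected FeatureMatrix) datasets."""
    reports = {}
    for name, fm in datasets.items():
        adj = batch_adj_r2(fm)
        reports[name] = ScoreReport(
            model_name=name,
            adj_r2=adj,
            n_samples=int((~fm.is_qc).sum()),
            n_batches=len(fm.batches),
        )
    return reports


def rank_models(reports: dict[str, ScoreReport]) -> pd.DataFrame:
    """Rank models ascending by score (lower = better correction).

    Ties on the score are broken by the mean adj-R^2 (consistency of the
    correction across the whole feature set), then by model name.
    """
    if not reports:
        raise ScoringError("rank_models needs at least one ScoreReport")
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "model": name,
                "score": rep.score,
                "raw_max_adj_r2": rep.raw_max,
                "mean_adj_r2": rep.mean_adj_r2,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["score", "mean_adj_r2", "model"], kind="mergesort", ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    table["rationale"] = [
        f"max batch adj-R^2 {r.score:.4f}; mean {r.mean_adj_r2:.4f} "
        "(lower is better)"
        for r in table.itertuples()
    ]
    return table


# ---------------------------------------------------------------------------
# sample-level diagnostics
# ---------------------------------------------------------------------------

def pca_scores(
    fm: FeatureMatrix, n_components: int = 2, scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA sample scores and explained-variance fractions.

    Columns are mean-centered and (by default) scaled to unit variance —
    metabolite intensities live on heterogeneous scales — then decomposed
    by SVD.  Component signs are fixed by forcing the largest-magnitude
    loading of each component positive, so results are reproducible across
    runs.  The returned frame carries the batch label per sample.
    """
    if n_components < 1:
        raise ScoringError("n_components must be a positive integer")
    values = fm.intensities.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise ScoringError("PCA needs a complete matrix; impute missing values first")
    if n_components > min(values.shape):
        raise ScoringError(
            f"n_components={n_components} exceeds min(n_samples, n_features)"
        )
    centered = values - values.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        centered = centered / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    U, Vt = U * flip, Vt * flip[:, None]
    scores = (U * S)[:, :n_components]
    explained = (S**2) / (S**2).sum()
    frame = pd.DataFrame(
        scores,
        index=fm.sample_ids,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    frame["batch"] = fm.batch
    frame["is_qc"] = fm.is_qc
    return frame, explained[:n_components]


def hca_dendrogram(
    fm: FeatureMatrix, method: str = "ward", standardize: bool = True
) -> np.ndarray:
    """Hierarchical clustering merge tree of the samples.

    Euclidean distance on (optionally per-feature standardized) samples;
    SciPy linkage matrix is returned (deterministic given input order;
    ties merge the lower-indexed pair first).  Cut it with
    ``scipy.cluster.hierarchy.fcluster`` to compare clusters with batch
    labels.
    """
    if method not in ("ward", "complete", "average"):
        raise ScoringError(f"unsupported linkage {method!r}")
    if fm.n_samples < 2:
        raise ScoringError("need at least 2 samples to cluster")
    values = fm.intensities.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise ScoringError("HCA needs a complete matrix; impute missing values first")
    if standardize:
        sd = values.std(axis=0, ddof=1)
        values = (values - values.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return linkage(pdist(values, metric="euclidean"), method=method)


# ---------------------------------------------------------------------------
# feature-level diagnostics
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Conventional star annotation for a p-value."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return ""


def feature_distribution_summary(
    fm: FeatureMatrix, feature_id: str, grid_size: int = 200
) -> dict:
    """Per-batch density curves and box/violin statistics for one feature.

    Returns, per batch: a Gaussian KDE (Silverman bandwidth) evaluated on
    a grid shared across batches, the five-number/box statistics, the raw
    per-sample points, and a two-sided t-test of the batch mean against
    the first batch with the conventional star annotation.  Batches with a
    single observation keep their point statistics but skip the KDE.
    """
    if feature_id not in fm.feature_ids:
        raise ScoringError(f"unknown feature {feature_id!r}")
    y = fm.intensities.loc[~fm.is_qc, feature_id]
    batch = fm.batch[~fm.is_qc]
    observed = y.dropna()
    lo, hi = float(observed.min()), float(observed.max())
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_size)

    first_batch = fm.batches[0]
    reference = y[batch == first_batch].dropna().to_numpy()
    per_batch = {}
    for b in fm.batches:
        vals = y[batch == b].dropna().to_numpy()
        entry: dict = {
            "n": int(vals.size),
            "points": vals,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "median": float(np.median(vals)) if vals.size else np.nan,
            "q1": float(np.percentile(vals, 25)) if vals.size else np.nan,
            "q3": float(np.percentile(vals, 75)) if vals.size else np.nan,
        }
        if vals.size >= 2 and np.ptp(vals) > 0:
            entry["density"] = stats.gaussian_kde(vals, bw_method="silverman")(grid)
        else:
            entry["density"] = None
            if vals.size < 2:
                logger.warning(
                    "batch %r has %d observation(s) of %r; KDE skipped",
                    b, vals.size, feature_id,
                )
        if b == first_batch or vals.size < 2 or reference.size < 2:
            entry["p_vs_first_batch"] = np.nan
            entry["stars"] = ""
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(vals, reference, equal_var=False).pvalue)
            entry["p_vs_first_batch"] = p
            entry["stars"] = significance_stars(p)
        per_batch[b] = entry
    return {"feature_id": feature_id, "grid": grid, "batches": per_batch}
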