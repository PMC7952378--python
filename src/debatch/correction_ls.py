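"""Location/scale batch correction models.

Two families are implemented, both operating feature-wise on a complete
(imputed) intensity table:

* **ber** — two-stage least squares.  Stage 1 fits each feature on the
  biological covariates plus batch indicators under a sample-size-weighted
  sum-to-zero constraint and subtracts the fitted batch offsets
  (location).  Stage 2 regresses the squared stage-1 residuals on batch
  indicators, yielding a per-batch residual scale that is divided out and
  replaced by the pooled scale.  A bagging variant stabilizes both
  parameter sets by averaging them over stratified bootstrap replicates
  and then applies the aggregated parameters once to the original data
  ("partial bagging": parameters are bagged, not predictions).

* **ComBat** — empirical-Bayes location/scale adjustment.  Features are
  standardized, per-batch location (gamma) and scale (delta^2) estimates
  are shrunk toward cross-feature priors — normal for gamma, inverse-gamma
  for delta^2, with hyperparameters by method of moments in the parametric
  mode, or by a weighted nonparametric posterior mean — and the shrunken
  estimators are used to remove the batch effect.  Borrowing strength
  across features guards against overfitting when batches are small.

QC samples are excluded from parameter estimation by default but are
corrected alongside the study samples with their batch's parameters, so
QC-based diagnostics stay comparable across models.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CorrectionResult, FeatureMatrix, FeatureTableError

logger = logging.getLogger("debatch")


class CorrectionError(ValueError):
    """Raised when a correction model cannot be fitted."""


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def build_covariate_design(
    fm: FeatureMatrix, covariates: Sequence[str] | pd.DataFrame | None
) -> pd.DataFrame | None:
    """Numeric covariate design aligned to ``fm`` samples (no intercept).

    ``covariates`` may be a list of covariate column names (looked up in
    ``fm.covariates``; categorical columns are dummy-encoded dropping the
    first level) or a ready-made numeric DataFrame.
    """
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        return covariates.loc[fm.sample_ids].astype(float)
    if fm.covariates is None:
        raise CorrectionError("covariates requested but FeatureMatrix has none")
    missing = [c for c in covariates if c not in fm.covariates.columns]
    if missing:
        raise CorrectionError(f"unknown covariate column(s): {missing}")
    cols = fm.covariates[list(covariates)]
    design = pd.get_dummies(cols, drop_first=True, dtype=float)
    return design.astype(float)


def _batch_onehot(batch: pd.Series, batches: list[str]) -> np.ndarray:
    return np.column_stack([(batch == b).to_numpy(float) for b in batches])


@dataclass
class _Stage1Fit:
    """Constrained least-squares fit of Y on [batch indicators + covariates]."""

    grand_mean: np.ndarray        # (G,)  mu_g: weighted mean of batch intercepts
    gamma: np.ndarray             # (I, G) batch offsets, weighted sum-to-zero
    beta: np.ndarray              # (p, G) covariate coefficients
    n_per_batch: np.ndarray       # (I,)  study samples per batch


def _fit_stage1(
    Y: np.ndarray, B: np.ndarray, X: np.ndarray | None
) -> _Stage1Fit:
    """Per-feature OLS of Y on full batch dummies (+ covariates).

    The batch intercepts are re-parameterized afterwards into a grand mean
    plus offsets whose sample-size-weighted sum is zero — the
    identifiability constraint used throughout.
    """
    n, G = Y.shape
    I = B.shape[1]
    D = B if X is None else np.hstack([B, X])
    coef, _, rank, _ = np.linalg.lstsq(D, Y, rcond=None)
    if rank < D.shape[1]:
        raise CorrectionError(
            "singular design: a batch indicator is confounded with a covariate "
            f"(rank {rank} < {D.shape[1]} columns)"
        )
    a = coef[:I]                       # per-batch intercepts (I, G)
    beta = coef[I:] if X is not None else np.zeros((0, G))
    n_i = B.sum(axis=0)
    mu = (n_i @ a) / n
    return _Stage1Fit(grand_mean=mu, gamma=a - mu, beta=beta, n_per_batch=n_i)


def _check_fit_inputs(fm: FeatureMatrix, min_batches: int = 1) -> None:
    if fm.intensities.isna().any().any():
        raise CorrectionError(
            "intensity table contains missing values; impute or filter first"
        )
    study = ~fm.is_qc
    batches = fm.batches
    if len(batches) < min_batches:
        raise CorrectionError(f"need at least {min_batches} batches")
    for b in batches:
        n_b = int(((fm.batch == b) & study).sum())
        if n_b < 2:
            raise CorrectionError(
                f"batch {b!r} has {n_b} non-QC sample(s); at least 2 required"
            )


# ---------------------------------------------------------------------------
# ber: two-stage least squares
# ---------------------------------------------------------------------------

@dataclass
class BerInternals:
    """Fitted ber parameters.

    ``location_coef`` holds the additive batch offsets (batch x feature)
    under the weighted sum-to-zero constraint; ``scale_factor`` the
    multiplicative per-batch residual scales from the stage-2 fit.
    """

    location_coef: pd.DataFrame           # batches x features
    scale_factor: pd.DataFrame            # batches x features, > 0
    covariate_coef: pd.DataFrame | None   # covariates x features
    grand_mean: pd.Series                 # per feature
    pooled_scale: pd.Series               # per feature
    n_boot: int = 0
    seed: int | None = None


def _ber_parameters(
    Y: np.ndarray, B: np.ndarray, X: np.ndarray | None
) -> tuple[_Stage1Fit, np.ndarray, np.ndarray]:
    """Stage-1 location fit and stage-2 per-batch residual scales.

    Returns the stage-1 fit, the per-(batch, feature) scale s_ig (sqrt of
    the batch mean of squared stage-1 residuals — the least-squares fit of
    squared residuals on batch indicators), and the pooled scale per
    feature.  Zero within-batch scales are mapped to the pooled scale so
    the scale step is inert for that (feature, batch).
    """
    fit = _fit_stage1(Y, B, X)
    resid = Y - fit.grand_mean - B @ fit.gamma
    if X is not None:
        resid -= X @ fit.beta
    n = Y.shape[0]
    n_i = fit.n_per_batch[:, None]
    s2 = (B.T @ resid**2) / n_i                      # (I, G) batch mean sq resid
    pooled = np.sqrt((fit.n_per_batch @ s2) / n)     # (G,)
    s = np.sqrt(s2)
    degenerate = s <= 0
    if degenerate.any():
        logger.warning(
            "ber: %d (feature, batch) cells with zero within-batch variance; "
            "scale step skipped there", int(degenerate.sum()),
        )
        s = np.where(degenerate, np.broadcast_to(pooled, s.shape), s)
        s = np.where(s <= 0, 1.0, s)  # all-constant feature: fully inert
    return fit, s, pooled


def _apply_ber(
    fm: FeatureMatrix,
    design: pd.DataFrame | None,
    mu: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    s: np.ndarray,
    pooled: np.ndarray,
) -> pd.DataFrame:
    """Apply fitted ber parameters to every sample (QC included)."""
    batches = fm.batches
    B_all = _batch_onehot(fm.batch, batches)
    Y_all = fm.intensities.to_numpy(float)
    base = mu + (0 if design is None else design.to_numpy(float) @ beta)
    resid = Y_all - base - B_all @ gamma
    scale = B_all @ (pooled / s)        # per-sample, per-feature rescale factor
    corrected = base + resid * scale
    return pd.DataFrame(corrected, index=fm.sample_ids, columns=fm.feature_ids)


def ber_correct(
    fm: FeatureMatrix,
    covariates: Sequence[str] | pd.DataFrame | None = None,
    include_qc: bool = False,
) -> CorrectionResult:
    """Two-stage least-squares batch correction.

    After correction with no covariates, every feature has identical
    per-batch means (the grand mean) and identical per-batch variances
    (the pooled variance) — an algebraic property of the two-stage fit.
    Biological covariates, when given, are estimated jointly with the
    batch offsets and re-added, so biology is preserved.
    """
    _check_fit_inputs(fm)
    design = build_covariate_design(fm, covariates)
    study = ~fm.is_qc if not include_qc else pd.Series(True, index=fm.sample_ids)
    batches = fm.batches
    Y = fm.intensities.loc[study].to_numpy(float)
    B = _batch_onehot(fm.batch[study], batches)
    X = None if design is None else design.loc[study].to_numpy(float)

    fit, s, pooled = _ber_parameters(Y, B, X)
    corrected = _apply_ber(fm, design, fit.grand_mean, fit.gamma, fit.beta, s, pooled)

    internals = BerInternals(
        location_coef=pd.DataFrame(fit.gamma, index=batches, columns=fm.feature_ids),
        scale_factor=pd.DataFrame(s, index=batches, columns=fm.feature_ids),
        covariate_coef=(
            None
            if design is None
            else pd.DataFrame(fit.beta, index=design.columns, columns=fm.feature_ids)
        ),
        grand_mean=pd.Series(fit.grand_mean, index=fm.feature_ids),
        pooled_scale=pd.Series(pooled, index=fm.feature_ids),
    )
    result = CorrectionResult(
        corrected=fm.with_intensities(corrected), model_name="ber", internals=internals
    )
    result.log("info", "BER_FIT", f"fitted {len(batches)} batches, {fm.n_features} features")
    return result


def ber_bagged(
    fm: FeatureMatrix,
    covariates: Sequence[str] | pd.DataFrame | None = None,
    n_boot: int = 150,
    seed: int | None = None,
    include_qc: bool = False,
) -> CorrectionResult:
    """ber with bootstrap-aggregated (bagged) batch parameters.

    For each of ``n_boot`` replicates, samples are resampled with
    replacement within each batch (stratified bootstrap) and the ber
    location and scale parameters are re-estimated; the per-(batch,
    feature) offsets and scales are aggregated by their mean over
    replicates, and the correction is applied once to the original data
    with the aggregated parameters.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise CorrectionError("n_boot must be a positive integer")
    _check_fit_inputs(fm)
    design = build_covariate_design(fm, covariates)
    study = ~fm.is_qc if not include_qc else pd.Series(True, index=fm.sample_ids)
    batches = fm.batches
    Y = fm.intensities.loc[study].to_numpy(float)
    B = _batch_onehot(fm.batch[study], batches)
    X = None if design is None else design.loc[study].to_numpy(float)
    rng = np.random.default_rng(seed)

    full_fit, _, _ = _ber_parameters(Y, B, X)

    batch_rows = [np.flatnonzero(B[:, i]) for i in range(len(batches))]
    gamma_acc = np.zeros((len(batches), Y.shape[1]))
    s_acc = np.zeros_like(gamma_acc)
    pooled_acc = np.zeros(Y.shape[1])
    for _ in range(n_boot):
        for attempt in range(100):
            rows = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True) for idx in batch_rows]
            )
            # a replicate where some batch collapses to one distinct sample
            # has no within-batch scale information: redraw it
            if all(
                np.unique(rows[B[rows, i] == 1]).size >= 2
                for i in range(len(batches))
            ):
                break
        else:
            raise CorrectionError(
                "could not draw a non-degenerate bootstrap replicate in 100 tries"
            )
        fit_b, s_b, pooled_b = _ber_parameters(
            Y[rows], B[rows], None if X is None else X[rows]
        )
        gamma_acc += fit_b.gamma
        s_acc += s_b
        pooled_acc += pooled_b
    gamma_bag = gamma_acc / n_boot
    s_bag = s_acc / n_boot
    pooled_bag = pooled_acc / n_boot

    corrected = _apply_ber(
        fm, design, full_fit.grand_mean, gamma_bag, full_fit.beta, s_bag, pooled_bag
    )
    internals = BerInternals(
        location_coef=pd.DataFrame(gamma_bag, index=batches, columns=fm.feature_ids),
        scale_factor=pd.DataFrame(s_bag, index=batches, columns=fm.feature_ids),
        covariate_coef=(
            None
            if design is None
            else pd.DataFrame(full_fit.beta, index=design.columns, columns=fm.feature_ids)
        ),
        grand_mean=pd.Series(full_fit.grand_mean, index=fm.feature_ids),
        pooled_scale=pd.Series(pooled_bag, index=fm.feature_ids),
        n_boot=n_boot,
        seed=seed,
    )
    result = CorrectionResult(
        corrected=fm.with_intensities(corrected),
        model_name="ber_bagged",
        internals=internals,
    )
    result.log("info", "BER_BAG", f"bagged {n_boot} stratified bootstrap replicates")
    return result


# ---------------------------------------------------------------------------
# ComBat: empirical-Bayes location/scale
# ---------------------------------------------------------------------------

@dataclass
class CombatInternals:
    """Every quantity of the EB procedure, on the standardized scale."""

    alpha: pd.Series                      # per-feature overall mean
    beta: pd.DataFrame | None             # covariate coefficients
    sigma2: pd.Series                     # per-feature pooled variance
    z: pd.DataFrame                       # standardized data (all samples)
    gamma_hat: pd.DataFrame               # batches x features
    delta2_hat: pd.DataFrame              # batches x features
    prior_gamma_mean: pd.Series           # per batch
    prior_gamma_var: pd.Series            # per batch
    prior_lambda: pd.Series | None        # per batch (parametric only)
    prior_theta: pd.Series | None         # per batch (parametric only)
    gamma_star: pd.DataFrame              # EB-adjusted location
    delta2_star: pd.DataFrame             # EB-adjusted scale
    mode: str = "parametric"
    n_iter: dict = field(default_factory=dict)   # per batch
    converged: bool = True


def _parametric_posterior(
    gamma_hat_i: np.ndarray,
    delta2_hat_i: np.ndarray,
    Z_i: np.ndarray,
    n_i: int,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, dict, int]:
    """Iterate the parametric EB fixed point for one batch.

    gamma* is the precision-weighted convex combination of the feature's own
    estimate and the cross-feature prior mean; delta2* the inverse-gamma
    posterior mean given gamma*.  Converges when the largest absolute
    relative change of either estimator drops below ``tol``.
    """
    g_bar = gamma_hat_i.mean()
    t2 = gamma_hat_i.var(ddof=1)
    V = delta2_hat_i.mean()
    S2 = delta2_hat_i.var(ddof=1)
    if S2 <= 0:
        raise CorrectionError(
            "cross-feature variance of delta^2 estimates is zero; "
            "parametric priors undefined (try more features)"
        )
    lam = (V**2 + 2 * S2) / S2
    theta = (V**3 + V * S2) / S2
    if lam <= 1:
        raise CorrectionError(
            f"inverse-gamma prior has lambda={lam:.3f} <= 1 (mean undefined); "
            "consider mode='nonparametric'"
        )
    gamma_star = gamma_hat_i.copy()
    delta2_star = delta2_hat_i.copy()
    trace = []
    for it in range(1, max_iter + 1):
        g_new = (n_i * t2 * gamma_hat_i + delta2_star * g_bar) / (
            n_i * t2 + delta2_star
        )
        sum2 = ((Z_i - g_new) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * sum2) / (n_i / 2 + lam - 1)
        change = max(
            np.max(np.abs(g_new - gamma_star) / (np.abs(gamma_star) + 1e-12)),
            np.max(np.abs(d_new - delta2_star) / (np.abs(delta2_star) + 1e-12)),
        )
        gamma_star, delta2_star = g_new, d_new
        trace.append(change)
        if change < tol:
            priors = {
                "gamma_mean": g_bar, "gamma_var": t2, "lambda": lam, "theta": theta
            }
            return gamma_star, delta2_star, priors, it
    raise CorrectionError(
        f"EB fixed point did not converge in {max_iter} iterations; "
        f"last 5 relative changes: {trace[-5:]}"
    )


def _nonparametric_posterior(
    gamma_hat_i: np.ndarray, delta2_hat_i: np.ndarray, Z_i: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out nonparametric posterior means for one batch.

    Each feature's (gamma*, delta2*) is the average of every *other*
    feature's (gamma_hat, delta2_hat) weighted by the Gaussian likelihood
    of this feature's batch data under those parameters; weights are
    renormalized to sum to one.
    """
    n_i, G = Z_i.shape
    # log-likelihood matrix L[g, g'] of feature g's data under params of g'
    sq = (Z_i[:, :, None] - gamma_hat_i[None, None, :]) ** 2   # (n, G, G')
    ll = -0.5 * sq.sum(axis=0) / delta2_hat_i[None, :] - 0.5 * n_i * np.log(
        2 * np.pi * delta2_hat_i
    )[None, :]
    np.fill_diagonal(ll, -np.inf)                              # leave-one-out
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    w /= w.sum(axis=1, keepdims=True)
    return w @ gamma_hat_i, w @ delta2_hat_i


def combat_correct(
    fm: FeatureMatrix,
    covariates: Sequence[str] | pd.DataFrame | None = None,
    mode: str = "parametric",
    tol: float = 1e-4,
    max_iter: int = 500,
    include_qc: bool = False,
) -> CorrectionResult:
    """Empirical-Bayes location/scale batch correction.

    Standardize each feature with the constrained least-squares fit,
    estimate per-batch location/scale on the standardized data, shrink the
    estimates toward cross-feature priors (parametric moment-matched
    normal/inverse-gamma, or a leave-one-out nonparametric posterior), and
    adjust with the shrunken estimators.  Covariates are retained in the
    adjusted data.
    """
    if mode not in ("parametric", "nonparametric"):
        raise CorrectionError(f"unknown mode {mode!r}")
    _check_fit_inputs(fm, min_batches=2)
    if fm.n_features < 2:
        raise CorrectionError(
            "empirical-Bayes priors need at least 2 features to pool across"
        )
    design = build_covariate_design(fm, covariates)
    study = ~fm.is_qc if not include_qc else pd.Series(True, index=fm.sample_ids)
    batches = fm.batches
    Y = fm.intensities.loc[study].to_numpy(float)
    B = _batch_onehot(fm.batch[study], batches)
    X = None if design is None else design.loc[study].to_numpy(float)
    n, G = Y.shape

    # step 1: standardize
    fit = _fit_stage1(Y, B, X)
    resid = Y - fit.grand_mean - B @ fit.gamma
    if X is not None:
        resid -= X @ fit.beta
    sigma2 = (resid**2).mean(axis=0)
    if np.any(sigma2 <= 0):
        bad = fm.feature_ids[np.flatnonzero(sigma2 <= 0)]
        raise CorrectionError(f"zero residual variance for feature(s): {list(bad)}")
    sigma = np.sqrt(sigma2)

    Y_all = fm.intensities.to_numpy(float)
    base_all = fit.grand_mean + (
        0 if design is None else design.to_numpy(float) @ fit.beta
    )
    Z_all = (Y_all - base_all) / sigma
    Z_study = Z_all[study.to_numpy()]

    # step 2: per-batch estimates and EB shrinkage
    n_i = fit.n_per_batch.astype(int)
    gamma_hat = np.vstack([Z_study[B[:, i] == 1].mean(axis=0) for i in range(len(batches))])
    delta2_hat = np.vstack(
        [Z_study[B[:, i] == 1].var(axis=0, ddof=1) for i in range(len(batches))]
    )
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    prior_g_mean, prior_g_var = [], []
    prior_lam: list[float] | None = [] if mode == "parametric" else None
    prior_theta: list[float] | None = [] if mode == "parametric" else None
    n_iter: dict[str, int] = {}
    for i, b in enumerate(batches):
        Z_i = Z_study[B[:, i] == 1]
        if mode == "parametric":
            g_st, d_st, priors, its = _parametric_posterior(
                gamma_hat[i], delta2_hat[i], Z_i, int(n_i[i]), tol, max_iter
            )
            prior_lam.append(priors["lambda"])
            prior_theta.append(priors["theta"])
            prior_g_mean.append(priors["gamma_mean"])
            prior_g_var.append(priors["gamma_var"])
            n_iter[b] = its
        else:
            g_st, d_st = _nonparametric_posterior(gamma_hat[i], delta2_hat[i], Z_i)
            prior_g_mean.append(float(gamma_hat[i].mean()))
            prior_g_var.append(float(gamma_hat[i].var(ddof=1)))
            n_iter[b] = 0
        gamma_star[i] = g_st
        delta2_star[i] = d_st

    # step 3: adjust with the shrunken estimators
    B_all = _batch_onehot(fm.batch, batches)
    adj = (Z_all - B_all @ gamma_star) / np.sqrt(B_all @ delta2_star)
    corrected = adj * sigma + base_all

    bi = pd.Index(batches, name="batch")
    internals = CombatInternals(
        alpha=pd.Series(fit.grand_mean, index=fm.feature_ids),
        beta=(
            None
            if design is None
            else pd.DataFrame(fit.beta, index=design.columns, columns=fm.feature_ids)
        ),
        sigma2=pd.Series(sigma2, index=fm.feature_ids),
        z=pd.DataFrame(Z_all, index=fm.sample_ids, columns=fm.feature_ids),
        gamma_hat=pd.DataFrame(gamma_hat, index=bi, columns=fm.feature_ids),
        delta2_hat=pd.DataFrame(delta2_hat, index=bi, columns=fm.feature_ids),
        prior_gamma_mean=pd.Series(prior_g_mean, index=bi),
        prior_gamma_var=pd.Series(prior_g_var, index=bi),
        prior_lambda=None if prior_lam is None else pd.Series(prior_lam, index=bi),
        prior_theta=None if prior_theta is None else pd.Series(prior_theta, index=bi),
        gamma_star=pd.DataFrame(gamma_star, index=bi, columns=fm.feature_ids),
        delta2_star=pd.DataFrame(delta2_star, index=bi, columns=fm.feature_ids),
        mode=mode,
        n_iter=n_iter,
        converged=True,
    )
    result = CorrectionResult(
        corrected=fm.with_intensities(
            pd.DataFrame(corrected, index=fm.sample_ids, columns=fm.feature_ids)
        ),
        model_name=f"combat_{mode}",
        internals=internals,
    )
    result.log("info", "COMBAT_FIT", f"{mode} EB fit over {len(batches)} batches")
    return result


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

MODEL_NAMES = (
    "ber",
    "ber_bagged",
    "combat_parametric",
    "combat_nonparametric",
    "qc_lowess",
)


def correct(
    fm: FeatureMatrix, model_name: str, **options
) -> CorrectionResult:
    """Dispatch to a correction model by name.

    Valid names: ``ber``, ``ber_bagged``, ``combat_parametric``,
    ``combat_nonparametric``, ``qc_lowess``.  Unknown names raise with the
    closest valid suggestion.
    """
    from .qc_lowess import lowess_correct  # local import: avoids a cycle

    dispatch = {
        "ber": ber_correct,
        "ber_bagged": ber_bagged,
        "combat_parametric": lambda f, **o: combat_correct(f, mode="parametric", **o),
        "combat_nonparametric": lambda f, **o: combat_correct(
            f, mode="nonparametric", **o
        ),
        "qc_lowess": lowess_correct,
    }
    if model_name not in dispatch:
        hint = difflib.get_close_matches(model_name, MODEL_NAMES, n=1, cutoff=0.4)
        suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
        raise CorrectionError(
            f"unknown model {model_name!r}; valid models: {MODEL_NAMES}{suggestion}"
        )
    result = dispatch[model_name](fm, **options)
    result.model_name = model_name
    return result
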