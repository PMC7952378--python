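# Methods

## The problem and the model

Multi-batch LC–MS acquisitions superimpose two kinds of analytical
variation on every feature: a between-batch location/scale effect (the
instrument responds at a different level and spread in each batch) and a
within-batch drift over injection order. All corrections here work on the
log2 scale, feature by feature, under the location/scale model

    Y_ijg = α_g + X_j β_g + γ_ig + δ_ig ε_ijg

where `g` indexes features, `i` batches, `j` samples, `X` holds optional
biological covariates, `γ_ig` is the additive batch offset and `δ_ig` the
multiplicative batch scale. Identifiability is fixed throughout by the
sample-size-weighted sum-to-zero constraint `Σ_i n_i γ_ig = 0`, so `α_g`
is the weighted grand mean. QC injections are excluded from all parameter
estimation by default and corrected afterwards with their batch's
parameters, which keeps QC-based diagnostics comparable between models; a
flag includes them.

## ber: two-stage least squares

Stage 1 fits each feature on full batch indicators plus covariates by
ordinary least squares and re-parameterizes the batch intercepts into the
weighted grand mean and constrained offsets, which are subtracted. Stage 2
is the least-squares fit of the squared stage-1 residuals on batch
indicators, whose fitted values are the per-batch mean squared residuals
`ŝ²_ig`; residuals are divided by `ŝ_ig` and multiplied by the pooled
scale (the weighted mean of `ŝ²_ig` over batches). The covariate fit and
grand mean are then restored. With no covariates this makes the corrected
per-batch means and variances algebraically equal — the property the unit
tests assert at 1e-8/1e-6 — and the model is exactly idempotent.

Degenerate case: a (feature, batch) cell with zero within-batch variance
would make the scale step divide by zero; the scale factor is replaced by
the pooled scale there (the step becomes inert) and a warning is logged.

**Bagging.** The bagged variant draws stratified bootstrap replicates
(resampling with replacement within each batch; a replicate in which any
batch collapses to fewer than two distinct samples is redrawn, at most 100
times), refits the stage-1/stage-2 parameters on each replicate, and
averages `γ` and `ŝ` over replicates. This is partial bagging: the
*parameters* are aggregated and the correction is applied once to the
original data with the aggregated parameters, rather than averaging
corrected datasets. The grand mean and covariate coefficients come from
the full-data fit — they are not what bagging is meant to stabilize. The
default of 150 replicates balances stabilization against cost; the
bootstrap-consistency test shows the bagged offsets converge to the plain
ber offsets at the expected 1/√n_boot rate.

## ComBat: empirical-Bayes location/scale

Step 1 standardizes each feature with the same constrained fit:
`σ̂²_g` is the mean squared residual (denominator n) and
`Z = (Y − α̂ − Xβ̂)/σ̂`. Step 2 estimates `γ̂_ig` (batch mean of Z) and
`δ̂²_ig` (batch variance, n−1). Parametric priors are moment-matched
across features per batch: normal for `γ` (mean γ̄_i, variance τ̄²_i) and
inverse-gamma for `δ²` with `λ̄_i = (V̄² + 2S²)/S²`,
`θ̄_i = (V̄³ + V̄S²)/S²` from the cross-feature mean V̄ and variance S² of
`δ̂²`. The posterior fixed point

    γ*_ig  = (n_i τ̄² γ̂_ig + δ*²_ig γ̄_i) / (n_i τ̄² + δ*²_ig)
    δ*²_ig = (θ̄_i + ½ Σ_j (Z_ijg − γ*_ig)²) / (n_i/2 + λ̄_i − 1)

is iterated until the largest absolute relative change drops below `tol`
(default 1e-4, the customary stopping rule for this iteration; `max_iter`
500, non-convergence raises with the change trace). `γ*` is a convex
combination of `γ̂_ig` and `γ̄_i`, which the tests check for every cell.
`λ̄_i ≤ 1` leaves the inverse-gamma mean undefined and raises with a
pointer to the nonparametric mode.

The nonparametric mode replaces the fixed point with a weighted posterior
mean: feature `g`'s `(γ*, δ*²)` in batch `i` averages every *other*
feature's `(γ̂, δ̂²)` weighted by the Gaussian likelihood of `g`'s batch-i
data under those parameters (leave-one-out, weights renormalized to one —
self-weighting would bias the posterior toward the feature's own
estimate). Step 3 adjusts with the shrunken estimators and restores
`α̂ + Xβ̂`. Covariates always re-enter the corrected data; there is no
reference batch — every batch shrinks toward the pooled parameters.

Because shrinkage never sets the batch means exactly equal, ComBat is only
idempotent up to a re-shrinkage tolerance, and with few features the
nonparametric posterior leaves visible residual batch structure — both are
asserted as such rather than hidden.

## QC-lowess comparator

Per feature (and per batch by default — a drift curve rarely survives a
batch boundary, though a whole-run fit is available), a tricube-weighted
lowess (span 0.5, 2 robustness iterations) of the QC intensities on
injection order is evaluated at every sample's order by linear
interpolation, held constant beyond the first/last QC to avoid edge
blow-up. Correction is the ratio to the feature's median QC intensity on
the raw scale, or the equivalent subtraction on the log2 scale. Features
with fewer than 3 QC observations in any window, or a non-positive fitted
level on the raw scale, are dropped and reported — the structural
limitation of QC-based correction that the statistical models do not
share.

## Scoring and ranking

`batch_adj_r2` is the one-way ANOVA fit of intensity on batch:
`R² = SS_between/SS_total`, `adj-R² = 1 − (1 − R²)(n − 1)/(n − B)`, with
QCs excluded and missing entries dropped pairwise (per-feature n). A
zero-variance feature reports 0 with a warning. A model's score is the
maximum adj-R² over features clipped to [0, 1]; the unclipped maximum is
preserved because a negative maximum (the batch regression fits worse than
the intercept for every feature) is the signature of a complete
correction. Ranking is ascending by score, ties broken by the mean adj-R²
(consistency of the correction across all features), then by name.

Diagnostics: PCA on column-standardized data (metabolite intensities live
on heterogeneous scales) with component signs fixed by the
largest-loading-positive convention; Ward/complete/average hierarchical
clustering of Euclidean distances; per-feature per-batch Gaussian KDEs
(Silverman bandwidth) on a shared grid plus box statistics and Welch
t-tests against the first batch with the `* / ** / *** / ****` star
convention at 0.05/0.01/0.001/0.0001.

## Downstream statistics

`pearson_fisher` reports `z = atanh(r)` with CI `z ± z_{1−α/2}/√(n−3)` on
both the z and (tanh back-transformed) r scales. `association_scan` fits
`outcome ~ metabolite + covariates` per feature by OLS on the samples with
complete metadata and Bonferroni-adjusts the metabolite p-value across
features; a collinear design fails only that feature. `differential_analysis`
uses per-feature equal-variance t tests and Benjamini–Hochberg adjustment;
significance requires both `|log2FC| >` the cutoff (both tails; default
1.5) and adjusted p below α. Plain OLS deliberately replaces moderated
(limma-style) statistics: with dozens of samples per group the moderation
gain is marginal and the estimator stays transparent.

## Synthetic data generator

`simulate` draws data directly from the location/scale model on the log2
scale: `μ_g ~ N(18, 2²)` baselines (typical log2 peak-area magnitudes),
`γ_ig ~ N(0, gamma_sd²)`, `δ_ig ~ LogNormal(0, delta_log_sd)`, a linear
(optionally sinusoidal) within-batch drift with slope
`~ N(0, drift_slope_sd²)` per injection, a Bernoulli two-group contrast
`b_g ~ N(0, bio_effect_sd²)`, and noise `ε ~ N(0, noise_sd²)` scaled by
`δ_ig`. QC injections open and close every batch and recur every
`qc_every` study samples, carrying the pooled baseline (no group effect)
plus the batch/drift/scale effects. Entries more than `lod_offset` log2
units below the feature baseline are censored to missing.

Presets (sized to generate in well under a minute and exercise every code
path): `targeted_cohort` — 11 batches × 20 samples, 100 features, QCs
every 10, strong offsets (`gamma_sd` 2), mild scales (`delta_log_sd` 0.2),
noise 0.5, no censoring (targeted panels are rarely below LOD);
`untargeted_tissue` — 3 batches × 25 samples, 500 noisier features, QCs
every 8, with LOD censoring at 4 log2 units below baseline.

What the generator does *not* emulate: correlated features (metabolites of
one pathway co-vary in real data), non-Gaussian heavy-tailed noise,
retention-time-dependent drift shapes, batch-specific missingness
mechanisms other than left-censoring, and QCs that fail to represent the
study samples. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to every pathology of
real acquisitions.

## Numerical choices and limitations

* Least squares via `numpy.linalg.lstsq`; a rank-deficient design (batch
  confounded with a covariate) raises rather than silently pseudo-inverting.
* Fixed-point convergence is relative with a 1e-12 guard in the
  denominator; the nonparametric weights are computed with a log-sum-exp
  shift for stability.
* Hierarchical clustering ties merge the lower-indexed pair first (SciPy's
  deterministic behavior); PCA signs are deterministic as described.
* Corrections require a complete matrix — impute (half-minimum by default;
  missingness in MS data is predominantly left-censored, and the original
  estimation algorithm is undocumented, so the LOD-style convention is the
  package's choice; correlation-kNN optional) or filter first.
* The adj-R² score is a max statistic: it tracks the worst feature, by
  design, and can be driven by a single outlier feature; the mean adj-R²
  in the report is the complementary consistency view.
* `ber` on a single batch is the identity; ComBat requires ≥ 2 batches and
  ≥ 2 features (the priors pool across features).
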