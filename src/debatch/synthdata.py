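"""Seeded generator of multi-batch metabolomics datasets with ground truth.

Emulates the structure of a long LC-MS acquisition: several analytical
batches with per-feature additive (location) and multiplicative (scale)
batch effects, a linear (optionally sinusoidal) signal drift over
injection order within each batch, pooled QC samples interleaved at a
fixed cadence, a two-group biological contrast, and below-LOD
left-censoring.  Intensities are generated directly on the log2 scale —
the scale every correction operates on — via

    y_ijg = mu_g + group_j * b_g + gamma_ig
            + drift_ig * (order_j - mean order of batch i)
            + delta_ig * eps,     eps ~ N(0, noise_sd^2)

QC samples are pooled aliquots: they carry the feature baseline (no
group effect) plus the same batch, drift and scale effects.  All truth
parameters are returned so estimator recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import LOG2, FeatureMatrix


class SimulationError(ValueError):
    """Raised for impossible simulation configurations."""


@dataclass
class SimConfig:
    """Generator settings; distributions are per-feature (x per-batch).

    All intensity-scale parameters are in log2 units.  ``gamma_sd`` is the
    SD of the additive batch offsets, ``delta_log_sd`` the log-SD of the
    multiplicative (log-normal, median 1) batch scale factors,
    ``drift_slope_sd`` the SD of the per-(feature, batch) linear drift
    slope per injection, ``bio_effect_sd`` the SD of the two-group
    contrast, and ``lod_offset`` (optional) censors entries more than that
    many log2 units below the feature baseline, mimicking the limit of
    detection.
    """

    n_batches: int = 3
    samples_per_batch: int = 20
    n_features: int = 50
    qc_every: int = 10
    group_fraction: float = 0.5
    mu_mean: float = 18.0
    mu_sd: float = 2.0
    bio_effect_sd: float = 0.5
    gamma_sd: float = 2.0
    delta_log_sd: float = 0.2
    drift_slope_sd: float = 0.05
    drift_shape: str = "linear"  # or "sinusoidal"
    noise_sd: float = 0.5
    lod_offset: float | None = None

    def validate(self) -> None:
        if self.n_batches < 1:
            raise SimulationError("n_batches must be >= 1")
        if self.samples_per_batch < 2:
            raise SimulationError("samples_per_batch must be >= 2")
        if self.n_features < 1:
            raise SimulationError("n_features must be >= 1")
        if self.qc_every < 1:
            raise SimulationError("qc_every must be >= 1")
        if not 0 <= self.group_fraction <= 1:
            raise SimulationError("group_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        if self.drift_shape not in ("linear", "sinusoidal"):
            raise SimulationError(f"unknown drift_shape {self.drift_shape!r}")


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind one simulated dataset."""

    mu: pd.Series                      # per-feature baseline (log2)
    b: pd.Series                       # per-feature group contrast (log2)
    gamma_true: pd.DataFrame           # batches x features additive offsets
    delta_true: pd.DataFrame           # batches x features scale factors (> 0)
    drift_slope: pd.DataFrame          # batches x features slope per injection
    lod: pd.Series                     # per-feature detection limit (-inf if none)
    noise_sd: float = 0.5
    seed: int | None = None
    config: dict = field(default_factory=dict)


PRESETS = {
    # scaled-down analogue of a year-long targeted plasma cohort:
    # many small batches, QCs every 10 injections, complete data
    "targeted_cohort": SimConfig(
        n_batches=11,
        samples_per_batch=20,
        n_features=100,
        qc_every=10,
        gamma_sd=2.0,
        delta_log_sd=0.2,
        drift_slope_sd=0.05,
        noise_sd=0.5,
        lod_offset=None,
    ),
    # scaled-down analogue of an untargeted tissue profiling run:
    # few large batches, many noisy features, below-LOD censoring
    "untargeted_tissue": SimConfig(
        n_batches=3,
        samples_per_batch=25,
        n_features=500,
        qc_every=8,
        gamma_sd=2.0,
        delta_log_sd=0.3,
        drift_slope_sd=0.05,
        noise_sd=0.7,
        lod_offset=4.0,
    ),
}


def preset(name: str) -> SimConfig:
    """A documented, scaled-down study configuration by name."""
    if name not in PRESETS:
        raise SimulationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    cfg = PRESETS[name]
    return SimConfig(**asdict(cfg))


def simulate(
    config: SimConfig | str | None = None, seed: int | None = None
) -> tuple[FeatureMatrix, SimulationTruth]:
    """Generate one dataset plus its ground truth; reproducible given seed.

    Within each batch, a QC injection opens the run, another follows every
    ``qc_every`` study samples, and one closes the run, so the drift curve
    is bracketed.  Injection order is global and strictly increasing over
    the whole acquisition.
    """
    if config is None:
        config = SimConfig()
    elif isinstance(config, str):
        config = preset(config)
    config.validate()
    rng = np.random.default_rng(seed)

    G = config.n_features
    I = config.n_batches
    features = pd.Index([f"F{g + 1:04d}" for g in range(G)], name="feature_id")
    batches = pd.Index([f"B{i + 1:02d}" for i in range(I)], name="batch")

    mu = rng.normal(config.mu_mean, config.mu_sd, G)
    b = rng.normal(0.0, config.bio_effect_sd, G)
    gamma = rng.normal(0.0, config.gamma_sd, (I, G)) if config.gamma_sd > 0 else np.zeros((I, G))
    delta = (
        rng.lognormal(0.0, config.delta_log_sd, (I, G))
        if config.delta_log_sd > 0
        else np.ones((I, G))
    )
    drift = (
        rng.normal(0.0, config.drift_slope_sd, (I, G))
        if config.drift_slope_sd > 0
        else np.zeros((I, G))
    )

    rows = []
    order = 0
    for i in range(I):
        # QC bracketing: open the batch, then one every qc_every samples,
        # then close it
        for s in range(config.samples_per_batch):
            if s % config.qc_every == 0:
                order += 1
                rows.append((i, order, True, np.nan))
            order += 1
            rows.append((i, order, False, rng.random() < config.group_fraction))
        order += 1
        rows.append((i, order, True, np.nan))

    batch_idx = np.array([r[0] for r in rows])
    orders = np.array([r[1] for r in rows], float)
    is_qc = np.array([r[2] for r in rows])
    group = np.array([0.0 if r[3] is np.nan else float(r[3]) for r in rows])
    group[is_qc] = 0.0
    n_total = len(rows)

    centered = np.empty(n_total)
    for i in range(I):
        in_i = batch_idx == i
        centered[in_i] = orders[in_i] - orders[in_i].mean()
    drift_term = drift[batch_idx] * centered[:, None]
    if config.drift_shape == "sinusoidal":
        span = np.array(
            [np.ptp(orders[batch_idx == i]) or 1.0 for i in range(I)]
        )[batch_idx]
        drift_term = drift[batch_idx] * (
            span[:, None] / (2 * np.pi) * np.sin(2 * np.pi * centered[:, None] / span[:, None])
        )

    eps = rng.normal(0.0, config.noise_sd, (n_total, G))
    y = (
        mu
        + group[:, None] * b
        + gamma[batch_idx]
        + drift_term
        + delta[batch_idx] * eps
    )

    lod = np.full(G, -np.inf) if config.lod_offset is None else mu - config.lod_offset
    censored = y < lod
    y = np.where(censored, np.nan, y)

    sample_ids = pd.Index(
        [
            f"{'QC' if q else 'S'}{k + 1:04d}"
            for k, q in enumerate(is_qc)
        ],
        name="sample_id",
    )
    covariates = pd.DataFrame(
        {
            "group": np.where(is_qc, np.nan, group),
            "age": np.where(is_qc, np.nan, rng.normal(50, 10, n_total).round(1)),
            "sex": np.where(is_qc, np.nan, rng.integers(0, 2, n_total).astype(float)),
        },
        index=sample_ids,
    )
    fm = FeatureMatrix(
        intensities=pd.DataFrame(y, index=sample_ids, columns=features),
        batch=pd.Series(batches[batch_idx], index=sample_ids),
        injection_order=pd.Series(orders.astype(int), index=sample_ids),
        is_qc=pd.Series(is_qc, index=sample_ids),
        covariates=covariates,
        scale_flag=LOG2,
    )
    truth = SimulationTruth(
        mu=pd.Series(mu, index=features),
        b=pd.Series(b, index=features),
        gamma_true=pd.DataFrame(gamma, index=batches, columns=features),
        delta_true=pd.DataFrame(delta, index=batches, columns=features),
        drift_slope=pd.DataFrame(drift, index=batches, columns=features),
        lod=pd.Series(lod, index=features),
        noise_sd=config.noise_sd,
        seed=seed,
        config=asdict(config),
    )
    return fm, truth


def raw_scale(fm: FeatureMatrix) -> FeatureMatrix:
    """Exponentiate a simulated log2 table back to the raw intensity scale."""
    out = fm.with_intensities(2.0 ** fm.intensities)
    out.scale_flag = "raw"
    return out
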