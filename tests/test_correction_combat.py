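"""Empirical-Bayes correction: fixed-point oracle, shrinkage, consistency."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from debatch import CorrectionError, combat_correct, correct, simulate
from debatch.synthdata import SimConfig

from conftest import make_fm


def combat_oracle(values, batches, tol=1e-10, max_iter=10000):
    """Scalar re-implementation of the parametric EB adjustment.

    Standardize each feature with batch means and the pooled residual
    variance, estimate per-batch location/scale of the standardized data,
    moment-match normal and inverse-gamma priors across features, iterate
    the posterior fixed point, and adjust.  Plain Python loops, written
    independently of the package's vectorized implementation.
    """
    values = np.asarray(values, float)
    b = np.asarray(batches)
    labels = list(dict.fromkeys(batches))
    n, G = values.shape
    n_i = {u: int((b == u).sum()) for u in labels}

    alpha = np.empty(G)
    sigma = np.empty(G)
    Z = np.empty_like(values)
    for g in range(G):
        y = values[:, g]
        means = {u: y[b == u].mean() for u in labels}
        alpha[g] = sum(n_i[u] * means[u] for u in labels) / n
        resid = np.array([y[k] - means[b[k]] for k in range(n)])
        sigma[g] = np.sqrt((resid**2).mean())
        Z[:, g] = (y - alpha[g]) / sigma[g]

    out = np.empty_like(values)
    for u in labels:
        rows = b == u
        g_hat = Z[rows].mean(axis=0)
        d2_hat = Z[rows].var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        V, S2 = d2_hat.mean(), d2_hat.var(ddof=1)
        lam = (V**2 + 2 * S2) / S2
        theta = (V**3 + V * S2) / S2
        g_star, d2_star = g_hat.copy(), d2_hat.copy()
        for _ in range(max_iter):
            g_new = (n_i[u] * t2 * g_hat + d2_star * g_bar) / (
                n_i[u] * t2 + d2_star
            )
            d2_new = np.array(
                [
                    (theta + 0.5 * ((Z[rows, g] - g_new[g]) ** 2).sum())
                    / (n_i[u] / 2 + lam - 1)
                    for g in range(G)
                ]
            )
            change = max(
                np.abs((g_new - g_star) / (np.abs(g_star) + 1e-12)).max(),
                np.abs((d2_new - d2_star) / (np.abs(d2_star) + 1e-12)).max(),
            )
            g_star, d2_star = g_new, d2_new
            if change < tol:
                break
        for g in range(G):
            out[rows, g] = (
                sigma[g] / np.sqrt(d2_star[g]) * (Z[rows, g] - g_star[g]) + alpha[g]
            )
    return out


@pytest.fixture
def seeded_three_feature():
    rng = np.random.default_rng(123)
    values = rng.normal(14, 1, (14, 3))
    values[:6] += np.array([2.0, -1.0, 0.5])
    return make_fm(values, "A" * 6 + "B" * 8)


class TestParametric:
    def test_matches_scalar_eb_oracle(self, seeded_three_feature):
        res = combat_correct(seeded_three_feature, mode="parametric", tol=1e-10)
        expected = combat_oracle(
            seeded_three_feature.intensities.to_numpy(),
            seeded_three_feature.batch.to_numpy(),
        )
        np.testing.assert_allclose(
            res.corrected.intensities.to_numpy(), expected, atol=1e-6
        )

    def test_shrinkage_is_convex_combination(self, small_simulated):
        fm, _ = small_simulated
        internals = combat_correct(fm, mode="parametric").internals
        for b in internals.gamma_hat.index:
            g_hat = internals.gamma_hat.loc[b]
            g_star = internals.gamma_star.loc[b]
            g_bar = internals.prior_gamma_mean[b]
            lo = np.minimum(g_hat, g_bar) - 1e-10
            hi = np.maximum(g_hat, g_bar) + 1e-10
            assert ((g_star >= lo) & (g_star <= hi)).all()

    def test_null_data_nearly_unchanged(self):
        cfg = SimConfig(
            n_batches=2,
            samples_per_batch=200,
            n_features=50,
            gamma_sd=0.0,
            delta_log_sd=0.0,
            drift_slope_sd=0.0,
            bio_effect_sd=0.0,
            noise_sd=0.5,
        )
        fm, _ = simulate(cfg, seed=5)
        res = combat_correct(fm, mode="parametric")
        diff = res.corrected.intensities.to_numpy() - fm.intensities.to_numpy()
        rms = np.sqrt((diff**2).mean(axis=0))
        sd = fm.intensities.to_numpy().std(axis=0)
        assert (rms < 0.05 * sd).all()

    def test_batch_mean_deviation_shrinks_with_n(self):
        deviations = []
        for n in (5, 20, 100):
            cfg = SimConfig(
                n_batches=3,
                samples_per_batch=n,
                n_features=60,
                drift_slope_sd=0.0,
                bio_effect_sd=0.0,
            )
            fm, _ = simulate(cfg, seed=9)
            corrected = combat_correct(fm, mode="parametric").corrected
            study = corrected.intensities.loc[~corrected.is_qc]
            means = study.groupby(corrected.batch[~corrected.is_qc]).mean()
            deviations.append(
                np.abs(means - means.mean()).to_numpy().max()
            )
        assert deviations[0] > deviations[1] > deviations[2]

    def test_idempotent_within_reshrinkage_tolerance(self, small_simulated):
        fm, _ = small_simulated
        once = combat_correct(fm, mode="parametric").corrected
        twice = combat_correct(once, mode="parametric").corrected
        sd = once.intensities.to_numpy().std()
        change = np.abs(
            twice.intensities.to_numpy() - once.intensities.to_numpy()
        )
        assert np.median(change) < 0.02 * sd

    def test_matches_reference_bioconductor_implementation(self, tmp_path):
        """Cross-check against the canonical EB implementation (sva) in R."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(31)
        values = rng.normal(16, 1, (18, 12))
        values[:8] += rng.normal(1.0, 0.8, 12)
        fm = make_fm(values, "A" * 8 + "B" * 10)
        ours = combat_correct(fm, mode="parametric", tol=1e-8)

        dat = fm.intensities.T  # features x samples, sva's orientation
        dat.to_csv(tmp_path / "dat.csv")
        (tmp_path / "batch.txt").write_text("\n".join(fm.batch) + "\n")
        script = tmp_path / "run_combat.R"
        script.write_text(
            "suppressMessages(library(sva))\n"
            f"dat <- as.matrix(read.csv('{tmp_path}/dat.csv', row.names=1, check.names=FALSE))\n"
            f"batch <- scan('{tmp_path}/batch.txt', what=character(), quiet=TRUE)\n"
            "out <- ComBat(dat=dat, batch=batch, mod=NULL, par.prior=TRUE)\n"
            f"write.csv(out, '{tmp_path}/out.csv')\n"
        )
        subprocess.run(
            ["Rscript", "--vanilla", str(script)], check=True, capture_output=True
        )
        reference = pd.read_csv(tmp_path / "out.csv", index_col=0).T
        np.testing.assert_allclose(
            ours.corrected.intensities.to_numpy(),
            reference.to_numpy(),
            atol=2e-3,
        )


class TestNonparametric:
    def test_agrees_with_parametric_on_large_balanced_data(self):
        cfg = SimConfig(
            n_batches=3,
            samples_per_batch=50,
            n_features=200,
            drift_slope_sd=0.0,
        )
        fm, _ = simulate(cfg, seed=13)
        par = combat_correct(fm, mode="parametric").corrected
        non = combat_correct(fm, mode="nonparametric").corrected
        diff = np.abs(par.intensities.to_numpy() - non.intensities.to_numpy())
        sd = fm.intensities.to_numpy().std()
        assert np.median(diff) < 0.05 * sd

    def test_reduces_batch_means_leaving_some_residual(self, small_simulated):
        # with few features the nonparametric posterior borrows from
        # neighboring features' estimates, so residual batch structure
        # remains (unlike the parametric mode) but is strongly reduced
        fm, _ = small_simulated
        corrected = combat_correct(fm, mode="nonparametric").corrected
        study = corrected.intensities.loc[~corrected.is_qc]
        means = study.groupby(corrected.batch[~corrected.is_qc]).mean()
        raw_study = fm.intensities.loc[~fm.is_qc]
        raw_means = raw_study.groupby(fm.batch[~fm.is_qc]).mean()
        dev = np.abs(means - means.mean()).to_numpy()
        raw_dev = np.abs(raw_means - raw_means.mean()).to_numpy()
        assert dev.max() < 0.5 * raw_dev.max()
        assert np.median(dev) < 0.2 * np.median(raw_dev)


class TestPreconditions:
    def test_two_features_minimum(self):
        fm = make_fm([[1.0], [2], [3], [4]], "AABB")
        with pytest.raises(CorrectionError, match="2 features"):
            combat_correct(fm)

    def test_two_batches_minimum(self):
        rng = np.random.default_rng(1)
        fm = make_fm(rng.normal(0, 1, (4, 3)), "AAAA")
        with pytest.raises(CorrectionError, match="batches"):
            combat_correct(fm)

    def test_unknown_mode(self, seeded_three_feature):
        with pytest.raises(CorrectionError, match="mode"):
            combat_correct(seeded_three_feature, mode="bayesian")

    def test_dispatch_equivalence(self, seeded_three_feature):
        a = correct(seeded_three_feature, "combat_parametric")
        b = combat_correct(seeded_three_feature, mode="parametric")
        assert a.corrected.intensities.equals(b.corrected.intensities)
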