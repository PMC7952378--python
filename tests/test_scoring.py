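"""Batch adj-R^2 score, model ranking, and sample/feature diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import silhouette_score

from debatch import (
    ScoreReport,
    ScoringError,
    batch_adj_r2,
    ber_correct,
    feature_distribution_summary,
    hca_dendrogram,
    model_score,
    pca_scores,
    rank_models,
    simulate,
)
from debatch.scoring_diagnostics import significance_stars
from debatch.synthdata import SimConfig

from conftest import make_fm


def anova_adj_r2_oracle(y, batches):
    """Direct sum-of-squares computation of the one-way adjusted R^2."""
    y = np.asarray(y, float)
    b = np.asarray(batches)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_between = sum(
        (b == u).sum() * (y[b == u].mean() - grand) ** 2 for u in set(b)
    )
    n, B = len(y), len(set(b))
    r2 = ss_between / ss_total
    return 1 - (1 - r2) * (n - 1) / (n - B)


class TestAdjR2:
    def test_two_batch_toy_closed_form(self, toy_two_batch):
        # SS_between=150, SS_total=154, adj = 1 - (4/154)(5/4)
        adj = batch_adj_r2(toy_two_batch)
        assert adj.iloc[0] == pytest.approx(1 - 5 / 154, abs=1e-12)
        assert adj.iloc[0] == pytest.approx(0.96753, abs=5e-6)

    def test_matches_anova_oracle_on_random_data(self, random_two_batch):
        adj = batch_adj_r2(random_two_batch)
        for j, feature in enumerate(random_two_batch.feature_ids):
            expected = anova_adj_r2_oracle(
                random_two_batch.intensities.iloc[:, j],
                random_two_batch.batch,
            )
            assert adj[feature] == pytest.approx(expected, abs=1e-12)

    def test_constant_feature_reported_as_zero(self):
        fm = make_fm([[5.0], [5], [5], [5]], "AABB")
        assert batch_adj_r2(fm).iloc[0] == 0.0

    def test_permuted_labels_null_mean_near_zero(self):
        rng = np.random.default_rng(29)
        n, G = 60, 500
        values = rng.normal(0, 1, (n, G))
        batches = rng.permutation(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        fm = make_fm(values, batches)
        adj = batch_adj_r2(fm)
        assert abs(adj.mean()) < 0.02

    def test_qc_samples_excluded(self):
        fm = make_fm(
            [[1], [2], [3], [11], [12], [13], [100]],
            "AAABBBB",
            is_qc=[False] * 6 + [True],
        )
        adj_with_qc_row = batch_adj_r2(fm)
        fm_no_qc = make_fm([[1], [2], [3], [11], [12], [13]], "AAABBB")
        assert adj_with_qc_row.iloc[0] == batch_adj_r2(fm_no_qc).iloc[0]

    def test_missing_excluded_pairwise(self):
        fm = make_fm([[1], [2], [np.nan], [11], [12], [13]], "AAABBB")
        expected = anova_adj_r2_oracle([1, 2, 11, 12, 13], list("AABBB"))
        assert batch_adj_r2(fm).iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_no_residual_dof_rejected(self):
        fm = make_fm([[1], [2]], "AB")
        with pytest.raises(ScoringError):
            batch_adj_r2(fm)


class TestModelScore:
    def test_max_convention(self):
        raw, score = model_score(pd.Series([0.3, 0.78, 0.1]))
        assert score == 0.78 and raw == 0.78

    def test_all_negative_clips_to_zero(self):
        raw, score = model_score(pd.Series([-0.2, -0.05]))
        assert score == 0.0
        assert raw == pytest.approx(-0.05)

    def test_single_feature(self):
        assert model_score(pd.Series([0.5]))[1] == 0.5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-1, max_value=1), min_size=1, max_size=30),
        st.floats(min_value=0, max_value=0.5),
    )
    def test_monotone_in_entrywise_increase(self, vec, bump):
        base = np.array(vec)
        _, s0 = model_score(base)
        _, s1 = model_score(np.minimum(base + bump, 1.0))
        assert s1 >= s0


def report(name, adj):
    return ScoreReport(
        model_name=name, adj_r2=pd.Series(adj), n_samples=60, n_batches=3
    )


class TestRanking:
    def test_ascending_by_score(self):
        table = rank_models(
            {
                "lowess": report("lowess", [0.78, 0.1]),
                "ber": report("ber", [0.005, 0.001]),
                "combat_parametric": report("combat_parametric", [0.008, 0.002]),
            }
        )
        assert list(table["model"]) == ["ber", "combat_parametric", "lowess"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_tie_broken_by_mean(self):
        table = rank_models(
            {
                "a": report("a", [0.5, 0.4]),
                "b": report("b", [0.5, 0.1]),
            }
        )
        assert list(table["model"]) == ["b", "a"]

    def test_single_model(self):
        table = rank_models({"only": report("only", [0.3])})
        assert list(table["rank"]) == [1]

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            rank_models({})


class TestPCA:
    def test_batch_shift_dominates_pc1(self):
        cfg = SimConfig(n_batches=2, samples_per_batch=30, n_features=40,
                        gamma_sd=4.0, noise_sd=0.3, drift_slope_sd=0.0)
        fm, _ = simulate(cfg, seed=3)
        study = fm.subset_features(fm.feature_ids)
        scores, explained = pca_scores(study, n_components=2)
        labels = pd.Categorical(scores.loc[~study.is_qc, "batch"]).codes
        sil = silhouette_score(
            scores.loc[~study.is_qc, ["PC1"]].to_numpy(), labels
        )
        assert sil > 0.5

    def test_scores_orthogonal_and_variance_nonincreasing(self, small_simulated):
        fm, _ = small_simulated
        scores, explained = pca_scores(fm, n_components=4)
        S = scores[["PC1", "PC2", "PC3", "PC4"]].to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1 + 1e-12

    def test_zero_components_rejected(self, small_simulated):
        fm, _ = small_simulated
        with pytest.raises(ScoringError):
            pca_scores(fm, n_components=0)

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, (6, 5))
        values[3] = values[0]
        fm = make_fm(values, "AAABBB")
        scores, _ = pca_scores(fm, n_components=2)
        np.testing.assert_allclose(
            scores.iloc[0][["PC1", "PC2"]].astype(float),
            scores.iloc[3][["PC1", "PC2"]].astype(float),
            atol=1e-10,
        )


class TestHCA:
    def test_two_separated_batches_recovered_by_cut(self):
        cfg = SimConfig(n_batches=2, samples_per_batch=15, n_features=30,
                        gamma_sd=6.0, noise_sd=0.3, drift_slope_sd=0.0)
        fm, _ = simulate(cfg, seed=8)
        Z = hca_dendrogram(fm)
        clusters = fcluster(Z, t=2, criterion="maxclust")
        batches = pd.Categorical(fm.batch).codes
        agreement = max(
            (clusters - 1 == batches).mean(), (2 - clusters == batches).mean()
        )
        assert agreement == 1.0

    def test_two_samples_single_merge(self):
        fm = make_fm([[0.0, 0], [3.0, 4]], "AB")
        Z = hca_dendrogram(fm, standardize=False)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_identical_samples_merge_at_zero(self):
        fm = make_fm([[1.0, 2], [1.0, 2], [5.0, 6]], "AAB")
        Z = hca_dendrogram(fm, standardize=False)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_rejected(self):
        fm = make_fm([[1.0]], "A")
        with pytest.raises(ScoringError):
            hca_dendrogram(fm)


class TestFeatureDistribution:
    def test_null_batches_overlap(self):
        # unit-variance null: per-batch KDEs agree to within kernel
        # sampling noise (sup of the difference ~ sqrt(2 f R(K)/(n h))
        # with a ~2.5-sigma envelope ~ 0.15 at n = 200)
        cfg = SimConfig(n_batches=3, samples_per_batch=200, n_features=3,
                        gamma_sd=0.0, delta_log_sd=0.0, drift_slope_sd=0.0,
                        bio_effect_sd=0.0, noise_sd=1.0)
        fm, _ = simulate(cfg, seed=14)
        summary = feature_distribution_summary(fm, "F0001")
        densities = [
            e["density"] for e in summary["batches"].values() if e["density"] is not None
        ]
        sup = max(
            np.abs(a - b).max() for a in densities for b in densities
        )
        assert sup < 0.15

    @pytest.mark.parametrize(
        "p,stars",
        [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****"), (0.2, "")],
    )
    def test_star_convention(self, p, stars):
        assert significance_stars(p) == stars

    def test_shifted_batch_flagged_significant(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(5, 1, 30)]
        ).reshape(-1, 1)
        fm = make_fm(values, "A" * 30 + "B" * 30)
        summary = feature_distribution_summary(fm, "F001")
        assert summary["batches"]["B"]["stars"] == "****"

    def test_single_sample_batch_degenerates_gracefully(self):
        fm = make_fm([[1.0], [2], [3], [9]], "AAAB")
        summary = feature_distribution_summary(fm, "F001")
        entry = summary["batches"]["B"]
        assert entry["density"] is None
        assert entry["median"] == 9.0

    def test_unknown_feature_rejected(self, small_simulated):
        fm, _ = small_simulated
        with pytest.raises(ScoringError):
            feature_distribution_summary(fm, "nope")
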