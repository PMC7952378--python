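"""Static diagnostic plots (PNG/SVG) over the scoring-module summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy.cluster.hierarchy import dendrogram

from .data_model import FeatureMatrix
from .scoring_diagnostics import (
    ScoreReport,
    feature_distribution_summary,
    hca_dendrogram,
    pca_scores,
)


def _save(fig: plt.Figure, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path


def pca_plot(fm: FeatureMatrix, out_path: str | Path, title: str = "PCA") -> Path:
    scores, explained = pca_scores(fm, n_components=2)
    fig, ax = plt.subplots(figsize=(6, 5))
    sns.scatterplot(
        data=scores, x="PC1", y="PC2", hue="batch", style="is_qc", s=30, ax=ax
    )
    ax.set_xlabel(f"PC1 ({explained[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({explained[1] * 100:.1f}%)")
    ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    return _save(fig, out_path)


def dendrogram_plot(
    fm: FeatureMatrix, out_path: str | Path, title: str = "HCA"
) -> Path:
    Z = hca_dendrogram(fm)
    batches = pd.Categorical(fm.batch)
    palette = sns.color_palette("husl", len(batches.categories))
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(Z, no_labels=True, ax=ax, link_color_func=lambda _: "gray")
    for tick, leaf in zip(ax.get_xticks(), ax.get_xticklabels()):
        pass  # leaves unlabeled; batch legend below
    handles = [
        plt.Line2D([], [], color=palette[i], marker="s", linestyle="")
        for i in range(len(batches.categories))
    ]
    ax.legend(handles, list(batches.categories), fontsize=7, ncol=4)
    ax.set_title(title)
    return _save(fig, out_path)


def density_plot(
    fm: FeatureMatrix, feature_id: str, out_path: str | Path
) -> Path:
    summary = feature_distribution_summary(fm, feature_id)
    fig, ax = plt.subplots(figsize=(6, 4))
    for b, entry in summary["batches"].items():
        if entry["density"] is not None:
            ax.plot(summary["grid"], entry["density"], label=b)
    ax.set_xlabel("intensity")
    ax.set_ylabel("density")
    ax.set_title(f"Per-batch distribution of {feature_id}")
    ax.legend(fontsize=7, ncol=3)
    return _save(fig, out_path)


def violin_plot(
    fm: FeatureMatrix, feature_id: str, out_path: str | Path
) -> Path:
    summary = feature_distribution_summary(fm, feature_id)
    frame = pd.DataFrame(
        {
            "batch": fm.batch[~fm.is_qc],
            "intensity": fm.intensities.loc[~fm.is_qc, feature_id],
        }
    ).dropna()
    fig, ax = plt.subplots(figsize=(7, 4))
    sns.violinplot(data=frame, x="batch", y="intensity", inner="box", ax=ax)
    sns.stripplot(
        data=frame, x="batch", y="intensity", size=2, color="black", alpha=0.5, ax=ax
    )
    top = frame["intensity"].max()
    for i, b in enumerate(fm.batches):
        stars = summary["batches"][b]["stars"]
        if stars:
            ax.text(i, top, stars, ha="center", fontsize=8)
    ax.set_title(f"{feature_id} by batch (stars: t-test vs first batch)")
    return _save(fig, out_path)


def scorebar_plot(reports: dict[str, ScoreReport], out_path: str | Path) -> Path:
    names = list(reports)
    scores = [reports[n].score for n in names]
    order = np.argsort(scores)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar([names[i] for i in order], [scores[i] for i in order], color="steelblue")
    ax.set_ylabel("max batch adj-R$^2$ (clipped at 0)")
    ax.set_title("Model performance score (lower is better)")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    return _save(fig, out_path)
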