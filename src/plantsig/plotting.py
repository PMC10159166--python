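"""Reporting figures for the benchmarking pipeline.

All functions take fitted objects/tables and write PNG files; they are
thin matplotlib wrappers and carry no computation of their own.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .synth import STIMULI


def plot_retention_curve(n_values, fractions, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(n_values, 100 * np.asarray(fractions), "o-")
    ax.set_xlabel("IQR multiplier n")
    ax.set_ylabel("data retained (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_correlation(corr: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scree(model, path: str | Path, threshold: float = 0.90) -> None:
    cum = model.cumulative_ratio()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, cum.size + 1), 100 * cum, "o-")
    ax.axhline(100 * threshold, ls="--", color="gray")
    ax.set_xlabel("number of principal components")
    ax.set_ylabel("cumulative explained variance (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_histograms(table: pd.DataFrame, path: str | Path,
                            by: str = "stimulus") -> None:
    """15-panel histogram grid, one panel per feature, split by label."""
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    fig, axes = plt.subplots(3, 5, figsize=(15, 8))
    for ax, col in zip(axes.ravel(), cols):
        for label, sub in table.groupby(by):
            ax.hist(sub[col].dropna(), bins=30, density=True, alpha=0.5,
                    label=str(label))
        ax.set_title(col, fontsize=8)
    axes.ravel()[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_confusion_heatmap(matrix: np.ndarray, path: str | Path,
                           title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(matrix, vmin=0, vmax=1, cmap="viridis")
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            ax.text(j, i, f"{matrix[i, j]:.2f}", ha="center", va="center",
                    color="w", fontsize=9)
    ax.set_xticks(range(3), STIMULI)
    ax.set_yticks(range(3), STIMULI)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_histograms(metrics_frame: pd.DataFrame, metric: str,
                           path: str | Path) -> None:
    """Per-classifier histograms of one metric, 15D vs 7D overlaid.

    The normal-fit mean of each space is annotated in the panel title.
    """
    classifiers = sorted(metrics_frame["classifier"].unique())
    n = len(classifiers)
    ncols = min(5, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax, name in zip(axes.ravel(), classifiers):
        sub = metrics_frame[metrics_frame["classifier"] == name]
        means = []
        for space, grp in sub.groupby("space"):
            ax.hist(grp[metric], bins=25, density=True, alpha=0.5, label=space)
            means.append(f"{space}: {grp[metric].mean():.3f}")
        ax.set_title(f"{name} ({', '.join(means)})", fontsize=7)
        ax.legend(fontsize=6)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.suptitle(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_metric_scatter(metrics_frame: pd.DataFrame, x: str, y: str,
                        path: str | Path) -> None:
    """Pairwise metric scatter, colored by feature space."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for space, grp in metrics_frame.groupby("space"):
        ax.scatter(grp[x], grp[y], s=6, alpha=0.4, label=space)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
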