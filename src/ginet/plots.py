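"""Report figures: selection-frequency barplot, class-wise boxplots, ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .classifier import EvaluationReport, ImportanceReport
from .dataset import CLASS_ORDER

__all__ = ["plot_selection_frequencies", "plot_class_distributions", "plot_roc"]

_CLASS_COLORS = {"SL": "#c0399f", "SV": "#2aa7b8", "NOT": "#8a8a8a"}


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_selection_frequencies(report: ImportanceReport, path: str | Path) -> Path:
    """Bar plot of per-feature selection fraction across the bootstrap models."""
    tab = report.table.sort_values("selection_fraction")
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1.5))
    colors = ["#2f6db3" if f in report.selected_features else "#b0b0b0" for f in tab.index]
    ax.barh(tab.index, tab["selection_fraction"], color=colors)
    ax.axvline(report.freq_threshold, color="k", ls="--", lw=1)
    ax.set_xlabel(f"fraction of {report.b} models selecting the feature (top {report.k_top})")
    ax.set_xlim(0, 1.02)
    return _save(fig, path)


def plot_class_distributions(
    df: pd.DataFrame, features: list[str], path: str | Path
) -> Path:
    """Per-class boxplots of feature values; ``df`` needs a ``label`` column."""
    n = len(features)
    fig, axes = plt.subplots(1, n, figsize=(2.6 * n, 3.2), squeeze=False)
    for ax, feat in zip(axes[0], features):
        data = [df.loc[df["label"] == c, feat].dropna() for c in CLASS_ORDER]
        box = ax.boxplot(data, tick_labels=CLASS_ORDER, patch_artist=True, showfliers=False)
        for patch, c in zip(box["boxes"], CLASS_ORDER):
            patch.set_facecolor(_CLASS_COLORS[c])
        ax.set_title(feat, fontsize=9)
    fig.tight_layout()
    return _save(fig, path)


def plot_roc(report: EvaluationReport, path: str | Path) -> Path:
    """One-vs-rest ROC curves, one per class, with their AUCs."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    for c, roc in report.roc_curves.items():
        ax.plot(roc.fpr, roc.tpr, color=_CLASS_COLORS.get(c, None),
                label=f"{c} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], color="k", lw=0.8, ls=":")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    return _save(fig, path)
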