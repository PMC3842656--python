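"""Plot helpers: pruning-cost curves, ROC panels, subset-frequency charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .classify import PruningReport, ROCCurve, SubsetSearchResult  # noqa: E402

__all__ = ["plot_pruning_costs", "plot_roc", "plot_feature_frequencies"]


def plot_pruning_costs(report: PruningReport, path: str | Path) -> None:
    """Cross-validation vs resubstitution cost over pruning levels, with the
    min + 1 SE cutoff and the selected level marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    levels = range(len(report.alphas))
    ax.errorbar(levels, report.cv_cost, yerr=report.cv_se, marker="o",
                label="cross-validation")
    ax.plot(levels, report.resub_cost, marker="s", label="resubstitution")
    ax.axhline(report.threshold, linestyle="--", color="grey",
               label="min + 1 SE")
    ax.axvline(report.best_level, linestyle=":", color="red",
               label=f"selected level {report.best_level}")
    ax.set_xlabel("pruning level")
    ax.set_ylabel("misclassification cost")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curves: dict[tuple[int, str], ROCCurve], path: str | Path) -> None:
    """One panel per class, one staircase per feature."""
    classes = sorted({c for _, c in curves})
    fig, axes = plt.subplots(1, len(classes), figsize=(4 * len(classes), 4),
                             squeeze=False)
    for ax, c in zip(axes[0], classes):
        for (f, cc), curve in curves.items():
            if cc == c:
                ax.plot(curve.fpr, curve.tpr, lw=0.8, label=f"w{f + 1}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_title(c)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_frequencies(result: SubsetSearchResult, path: str | Path,
                             top: int = 1000) -> None:
    """Occurrence frequency of each feature among the top-ranked subsets,
    full vs pruned trees side by side."""
    full = result.feature_frequencies("full", top)
    pruned = result.feature_frequencies("pruned", top)
    fig, ax = plt.subplots(figsize=(9, 4))
    x = range(len(full))
    ax.bar([i - 0.2 for i in x], full.values, width=0.4, label="full tree")
    ax.bar([i + 0.2 for i in x], pruned.values, width=0.4, label="pruned tree")
    ax.set_xticks(list(x))
    ax.set_xticklabels(full.index, rotation=60)
    ax.set_ylabel("occurrence frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
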