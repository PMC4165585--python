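"""SVG plots for panel outputs: per-group PMR dot plots and ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .panel_stats import RocResult


def plot_pmr_dots(pmrs: pd.DataFrame, cohort: pd.DataFrame, path: str | Path) -> Path:
    """Dot plot of PMR values per cohort group, one panel per gene."""
    df = pmrs.merge(cohort, on="sample")
    genes = sorted(df["gene"].unique())
    groups = sorted(df["group"].unique())
    fig, axes = plt.subplots(
        1, len(genes), figsize=(3.2 * len(genes), 3.4), sharey=True, squeeze=False
    )
    for ax, gene in zip(axes[0], genes):
        sub = df[df["gene"] == gene]
        for i, group in enumerate(groups):
            vals = sub.loc[sub["group"] == group, "pmr"]
            ax.plot([i] * len(vals), vals, "o", ms=3, alpha=0.6)
        ax.set_title(gene, fontsize=9)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups, rotation=90, fontsize=6)
    axes[0][0].set_ylabel("PMR (%)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)


def plot_roc(results: dict[str, RocResult], path: str | Path) -> Path:
    """Overlayed ROC curves, labelled with their AUCs."""
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    for name, roc in results.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC={roc.auc:.3f})", lw=1.2)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return Path(path)
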