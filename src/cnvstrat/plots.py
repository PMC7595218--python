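"""Diagnostic figures: gap curve and PC1-vs-PC2 scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cluster_engine import GapResult, PCAModel

__all__ = ["plot_gap_curve", "plot_pc_scatter"]


def plot_gap_curve(gap: GapResult, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(gap.k_values, gap.gap, yerr=gap.s_k, marker="o", capsize=3)
    ax.axvline(gap.chosen_k, color="grey", ls="--", lw=1)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("gap(k)")
    ax.set_title(f"gap statistic (B={gap.B}, rule={gap.rule}, chosen k={gap.chosen_k})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pc_scatter(pca: PCAModel, labels, path) -> None:
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, color in zip(sorted(set(labels.tolist())), ("tab:red", "tab:blue", "tab:green")):
        m = labels == lab
        ax.scatter(pca.scores[m, 0], pca.scores[m, 1], s=8, alpha=0.6, label=str(lab), c=color)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
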