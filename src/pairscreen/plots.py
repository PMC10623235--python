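"""Plot artifacts: ROC curves and pattern-probability heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pair_model import PairModel
from .roc import ROCCurve


def plot_roc(curves: dict[str, ROCCurve], path: str | Path) -> None:
    """Overlayed ROC polygons, one per instrument label."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        fpr = [1.0 - p.specificity for p in curve.points]
        tpr = [p.sensitivity for p in curve.points]
        ax.plot(fpr, tpr, marker="o", markersize=3, label=f"{label} (AUC {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey", linewidth=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pattern_heatmap(model: PairModel, threshold: float, path: str | Path) -> None:
    """4x4 heatmap of pattern probabilities with the decision boundary overlaid."""
    probs = model.pattern_probabilities()
    grid = np.zeros((4, 4))
    for (a, b), p in probs.items():
        grid[b, a] = p  # item i on x-axis, item j on y-axis
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(grid, origin="lower", cmap="RdBu_r", vmin=0, vmax=1)
    for (a, b), p in probs.items():
        positive = p >= threshold
        ax.text(a, b, f"{p:.3f}", ha="center", va="center",
                color="white" if positive else "black", fontsize=8)
    # outline predicted-positive cells
    for (a, b), p in probs.items():
        if p >= threshold:
            ax.add_patch(plt.Rectangle((a - 0.5, b - 0.5), 1, 1, fill=False,
                                       edgecolor="white", linewidth=2))
    ax.set_xticks(range(4))
    ax.set_yticks(range(4))
    ax.set_xlabel(f"item {model.pair.i} response")
    ax.set_ylabel(f"item {model.pair.j} response")
    ax.set_title(f"{model.pair}: P(screen positive), threshold >= {threshold:.3f}")
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
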