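"""Figures for the early-recognition performance sweep."""

from __future__ import annotations

import pandas as pd


def plot_prefix_sweep(table: pd.DataFrame, metric: str = "accuracy_pct", ax=None):
    """Accuracy (or macro F1) vs prefix fraction, one line per subject.

    ``table`` is the tidy frame from :func:`gaitdtw.evaluate.sweep_frame`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for subject, grp in table.groupby("subject"):
        grp = grp.sort_values("prefix_fraction")
        style = dict(lw=2.5, color="k") if subject == "pooled" else dict(lw=1, alpha=0.6)
        ax.plot(grp["prefix_fraction"] * 100, grp[metric], label=subject, **style)
    ax.set_xlabel("progression into gait cycle (%)")
    ax.set_ylabel("pooled accuracy (%)" if metric == "accuracy_pct" else "macro F1")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_confusion(confusion, ax=None):
    """3x3 confusion-count heatmap (rows = true, cols = predicted)."""
    import matplotlib.pyplot as plt

    from .types import MODE_ORDER

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(confusion, cmap="Blues")
    labels = [m.value for m in MODE_ORDER]
    ax.set_xticks(range(3), labels)
    ax.set_yticks(range(3), labels)
    for i in range(3):
        for j in range(3):
            ax.text(j, i, str(int(confusion[i][j])), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax
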