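"""Static plots for classifier evaluation and feature summaries."""

from __future__ import annotations

import pandas as pd

from .tolerability import AccuracyCurve, RocResult


def plot_roc(roc: RocResult, ax=None, label: str | None = None):
    """ROC curve with the chance diagonal; AUC in the legend."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    label = label or f"AUC = {roc.auc:.2f}"
    ax.plot(roc.fpr, roc.tpr, label=label)
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    return ax


def plot_accuracy_curve(curve: AccuracyCurve, ax=None):
    """Accuracy against score cutoff, with the optimal cutoff marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.cutoffs, curve.accuracy)
    ax.axvline(curve.optimal_cutoff, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("Score cutoff")
    ax.set_ylabel("Classification accuracy")
    return ax


def plot_median_by_count(medians: pd.Series, ax=None, xlabel: str = "count"):
    """Median score per feature count (e.g. median calcium score by number
    of G nucleotides)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(medians.index, medians.to_numpy(), "o-")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("Median score")
    return ax
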