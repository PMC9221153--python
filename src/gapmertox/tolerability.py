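"""Acute tolerability scoring, severity classes, and classifier evaluation.

After a single 100 ug ICV bolus, each mouse is observed for 1 h and scored
0-4 in five neurobehavioral categories (hyperactivity; decreased activity
and arousal; motor dysfunction/ataxia; abnormal posture and breathing;
tremor/convulsions).  The five scores sum to a per-mouse acute tolerability
score in [0, 20]; per-mouse totals are averaged over the 4-6 mice of a
treatment group to give the per-ASO score.

Severity bins partition [0, 20]:

    mild      [0, 4)
    moderate  [4, 7)
    marked    [7, 18]
    severe    (18, 20]

The binary task calls an ASO *acceptable* when its group-mean score is at
or below 4 and *toxic* otherwise.  (The published class figure draws the
mild bin as "<4" while the binary analysis states "at or below 4"; this
package follows the explicit "at or below 4" rule for the binary label and
keeps 4 in the moderate severity bin.)

Classifier evaluation treats *toxic* as the positive class, and the
predictor (calculated or measured calcium score) is oriented so that
higher values predict safer ASOs: an ASO is predicted toxic when its score
is at or below the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

SEVERITY_CLASSES = ("mild", "moderate", "marked", "severe")

N_CATEGORIES = 5
MAX_CATEGORY_SCORE = 4
MAX_TOTAL = N_CATEGORIES * MAX_CATEGORY_SCORE  # 20


def aggregate_tolerability(mice: Sequence[Sequence[int]]) -> float:
    """Group-mean acute tolerability score from per-mouse category scores.

    ``mice`` is a list (1-10 entries) of five category scores, each an
    integer in [0, 4]; each mouse's five scores are summed and the per-mouse
    totals averaged.
    """
    if not 1 <= len(mice) <= 10:
        raise ValueError(f"expected 1-10 mice, got {len(mice)}")
    totals = []
    for m, cats in enumerate(mice):
        cats = list(cats)
        if len(cats) != N_CATEGORIES:
            raise ValueError(f"mouse {m}: expected {N_CATEGORIES} categories")
        for c in cats:
            if int(c) != c or not 0 <= c <= MAX_CATEGORY_SCORE:
                raise ValueError(
                    f"mouse {m}: category score {c!r} outside [0, 4]"
                )
        totals.append(sum(cats))
    return float(np.mean(totals))


def classify_severity(score: float) -> str:
    """Severity class of a group-mean tolerability score (bins above)."""
    if not 0 <= score <= MAX_TOTAL:
        raise ValueError(f"tolerability score {score} outside [0, 20]")
    if score < 4:
        return "mild"
    if score < 7:
        return "moderate"
    if score <= 18:
        return "marked"
    return "severe"


def binary_label(score: float) -> str:
    """'acceptable' iff the tolerability score is at or below 4, else
    'toxic'."""
    if not 0 <= score <= MAX_TOTAL:
        raise ValueError(f"tolerability score {score} outside [0, 20]")
    return "acceptable" if score <= 4 else "toxic"


def _as_toxic(labels) -> np.ndarray:
    """Coerce labels to a boolean 'toxic' array.  Accepts booleans (True =
    toxic), 0/1 integers, or the strings 'toxic'/'acceptable'."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "b":
        return arr.astype(bool)
    if arr.dtype.kind in "iuf":
        return arr.astype(bool)
    toxic = arr == "toxic"
    acceptable = arr == "acceptable"
    if not np.all(toxic | acceptable):
        bad = arr[~(toxic | acceptable)][0]
        raise ValueError(f"unrecognized label {bad!r}")
    return toxic


@dataclass(frozen=True)
class RocResult:
    """ROC curve for the toxic-vs-acceptable task.

    ``cutoffs`` are on the predictor scale: at cutoff c the prediction is
    toxic iff predictor <= c.  ``auc`` equals the probability that a random
    toxic ASO scores lower than a random acceptable one (ties count 1/2).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    auc: float


def roc_analysis(predictor, labels) -> RocResult:
    """ROC curve and AUC for a higher-is-safer predictor against binary
    tolerability labels."""
    pred = np.asarray(predictor, dtype=float)
    toxic = _as_toxic(labels)
    if toxic.all() or not toxic.any():
        raise ValueError("both classes must be present for ROC analysis")
    # sklearn expects higher score = more positive; positive class is toxic
    # and low predictor values indicate toxicity, so negate.
    fpr, tpr, thresh = _sk_roc_curve(toxic, -pred)
    auc = float(roc_auc_score(toxic, -pred))
    return RocResult(fpr=fpr, tpr=tpr, cutoffs=-thresh, auc=auc)


@dataclass(frozen=True)
class AccuracyCurve:
    """Classification accuracy over a grid of score cutoffs.

    ``optimal_cutoff`` is the midpoint of the widest contiguous grid run
    achieving the maximal accuracy (ties broken toward the lowest run).
    """

    cutoffs: np.ndarray
    accuracy: np.ndarray
    optimal_cutoff: float
    max_accuracy: float


def accuracy_vs_cutoff(
    predictor, labels, cutoff_grid: Optional[Iterable[float]] = None
) -> AccuracyCurve:
    """Accuracy of the toxic/acceptable call as a function of the cutoff.

    At cutoff c, predicted acceptable iff predictor > c.  The default grid
    is the integers 0..200 (the calcium-score scale).
    """
    pred = np.asarray(predictor, dtype=float)
    toxic = _as_toxic(labels)
    if toxic.all() or not toxic.any():
        raise ValueError("both classes must be present")
    grid = (
        np.arange(0.0, 201.0)
        if cutoff_grid is None
        else np.asarray(list(cutoff_grid), dtype=float)
    )
    if grid.size == 0:
        raise ValueError("cutoff grid must be non-empty")
    acc = np.array(
        [np.mean((pred <= c) == toxic) for c in grid], dtype=float
    )
    best = acc.max()
    at_max = np.isclose(acc, best, rtol=0, atol=1e-12)
    # widest contiguous plateau of grid points at the maximum
    runs = []
    start = None
    for i, flag in enumerate(at_max):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(grid) - 1))
    s, e = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    return AccuracyCurve(
        cutoffs=grid,
        accuracy=acc,
        optimal_cutoff=float((grid[s] + grid[e]) / 2),
        max_accuracy=float(best),
    )


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and derived metrics at a fixed cutoff.

    Positive class = toxic; predicted toxic iff predictor <= cutoff.
    NPV is the fraction of predicted-acceptable ASOs that are truly
    acceptable.  Metrics with a zero denominator are NaN (with a warning).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)

    def __post_init__(self):
        def ratio(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator)")
                return float("nan")
            return num / den

        n = self.tp + self.fp + self.tn + self.fn
        object.__setattr__(self, "accuracy", ratio(self.tp + self.tn, n, "accuracy"))
        object.__setattr__(
            self, "sensitivity", ratio(self.tp, self.tp + self.fn, "sensitivity")
        )
        object.__setattr__(
            self, "specificity", ratio(self.tn, self.tn + self.fp, "specificity")
        )
        object.__setattr__(self, "ppv", ratio(self.tp, self.tp + self.fp, "PPV"))
        object.__setattr__(self, "npv", ratio(self.tn, self.tn + self.fn, "NPV"))

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "cutoff": self.cutoff,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def classification_report(predictor, labels, cutoff: float) -> ClassificationReport:
    """Confusion table and metrics at a fixed cutoff (predicted toxic iff
    predictor <= cutoff; positive class = toxic)."""
    pred = np.asarray(predictor, dtype=float)
    toxic = _as_toxic(labels)
    if toxic.all() or not toxic.any():
        raise ValueError("both classes must be present")
    predicted_toxic = pred <= cutoff
    return ClassificationReport(
        tp=int(np.sum(predicted_toxic & toxic)),
        fp=int(np.sum(predicted_toxic & ~toxic)),
        tn=int(np.sum(~predicted_toxic & ~toxic)),
        fn=int(np.sum(~predicted_toxic & toxic)),
        cutoff=float(cutoff),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared (k-1 df) p-value
    across >= 2 groups of scores."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)
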