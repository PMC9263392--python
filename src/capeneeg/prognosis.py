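"""Fixed-cutoff recovery classification and ROC evaluation of the D statistic.

A patient is predicted to recover (mGOS >= 3 at 12 months) when the
pain-minus-rest Cu-FPu difference statistic reaches the decision cutoff,
``D >= 0.07`` by default; the boundary is inclusive, reading the cutoff as
the least value that predicts recovery.  ROC analysis sweeps the observed D
values as thresholds under the same "positive iff D >= t" rule, with
trapezoidal AUC and the Youden operating point (max sensitivity +
specificity - 1, ties broken toward the smallest threshold, which favors
sensitivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateROCError

#: Decision cutoff on D used for prognostic classification.
DEFAULT_CUTOFF = 0.07


def classify(d: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Predict improvement iff ``d >= cutoff`` (inclusive boundary)."""
    if not math.isfinite(d):
        raise ValueError(f"D must be finite, got {d}")
    return d >= cutoff


def classify_many(d_values, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    d = np.asarray(d_values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("all D values must be finite")
    return d >= cutoff


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with sensitivity and specificity."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def confusion(predictions, outcomes) -> ConfusionSummary:
    """Confusion summary of predicted vs observed improvement labels."""
    pred = np.asarray(predictions, dtype=bool)
    outc = np.asarray(outcomes, dtype=bool)
    if pred.shape != outc.shape or pred.ndim != 1:
        raise ValueError("predictions and outcomes must be aligned 1-D vectors")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionSummary(
        tp=int(np.sum(pred & outc)),
        fp=int(np.sum(pred & ~outc)),
        tn=int(np.sum(~pred & ~outc)),
        fn=int(np.sum(~pred & outc)),
    )


@dataclass(frozen=True)
class ROCResult:
    """ROC sweep over observed thresholds, with AUC and Youden cutoff."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float


def roc(d_values, outcomes) -> ROCResult:
    """ROC analysis of D against improvement outcomes.

    Thresholds are the sorted unique D values plus a ``+inf`` sentinel
    (all-negative operating point); a case is called positive iff
    ``D >= threshold``.  AUC is the trapezoidal area under (FPR, TPR).
    """
    d = np.asarray(d_values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("d_values and outcomes must be aligned 1-D vectors")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateROCError(
            f"ROC needs both outcome classes (got {n_pos} positive, {n_neg} negative)"
        )
    thresholds = np.concatenate([np.unique(d), [np.inf]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = d >= t
        sens[i] = np.sum(pred & y) / n_pos
        spec[i] = np.sum(~pred & ~y) / n_neg
    # integrate TPR over FPR, adding the trivial all-positive corner (1, 1);
    # both rates are non-increasing along ascending thresholds, so reversing
    # that order traverses the ROC curve with FPR ascending
    fpr = np.concatenate([[1.0], 1.0 - spec])[::-1]
    tpr = np.concatenate([[1.0], sens])[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    youden_cutoff = float(thresholds[best[0]])  # smallest threshold among ties
    return ROCResult(thresholds, sens, spec, auc, youden_cutoff)
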