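"""Confusion-matrix metrics and operating-point selection.

Sensitivity/specificity are reported in percent, balanced accuracy (BAC)
is their arithmetic mean, and F1 = 2TP / (2TP + FN + FP).  The decision
threshold of a trained classifier is placed at the ROC operating point
maximizing validation BAC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN for the AF class, TN/FP for the non-AF class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)


@dataclass(frozen=True)
class MetricSet:
    """Se/Sp/BAC in percent, F1 in [0, 1]."""

    se: float
    sp: float
    bac: float
    f1: float


def confusion_counts(pred: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Count detections; ``labels`` is 1 for AF, ``pred`` is the decision."""
    pred = np.asarray(pred).astype(bool)
    labels = np.asarray(labels).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fn=int(np.sum(~pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
        fp=int(np.sum(pred & ~labels)),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Se, Sp, BAC (percent) and F1 from confusion counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be represented in the counts")
    se = 100.0 * c.tp / (c.tp + c.fn)
    sp = 100.0 * c.tn / (c.tn + c.fp)
    f1 = 2.0 * c.tp / (2.0 * c.tp + c.fn + c.fp) if c.tp + c.fn + c.fp else 1.0
    return MetricSet(se=se, sp=sp, bac=(se + sp) / 2.0, f1=f1)


def balanced_accuracy(pred: np.ndarray, labels: np.ndarray) -> float:
    """BAC in percent of a hard decision vector."""
    return compute_metrics(confusion_counts(pred, labels)).bac


def select_threshold(val_probs: np.ndarray, val_labels: np.ndarray) -> float:
    """Probability threshold maximizing validation balanced accuracy.

    Candidates are the midpoints between sorted distinct probabilities plus
    {0, 1}; a record is called AF when its probability strictly exceeds the
    threshold.  Among equally optimal candidates the smallest is returned,
    which maximizes sensitivity at the optimal BAC.
    """
    val_probs = np.asarray(val_probs, dtype=float)
    val_labels = np.asarray(val_labels)
    if len(np.unique(val_labels)) < 2:
        raise ValueError("validation set must contain both classes")
    uniq = np.unique(val_probs)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    best_thr, best_bac = 0.0, -np.inf
    for thr in candidates:
        bac = balanced_accuracy(val_probs > thr, val_labels)
        if bac > best_bac + 1e-12:
            best_bac, best_thr = bac, thr
    return float(best_thr)


def evaluate_model(model, X: np.ndarray, labels: np.ndarray,
                   strata: np.ndarray | None = None) -> pd.DataFrame:
    """Evaluate a thresholded model, optionally stratified by source dataset.

    Returns one row per stratum plus a ``Total`` row with columns
    (stratum, TP, FN, TN, FP, Se, Sp, BAC, F1).
    """
    pred = model.predict(X)
    labels = np.asarray(labels)
    rows = []

    def row(name: str, mask: np.ndarray) -> dict:
        c = confusion_counts(pred[mask], labels[mask])
        m = compute_metrics(c)
        return {"stratum": name, "TP": c.tp, "FN": c.fn, "TN": c.tn, "FP": c.fp,
                "Se": m.se, "Sp": m.sp, "BAC": m.bac, "F1": m.f1}

    if strata is not None:
        strata = np.asarray(strata)
        for name in pd.unique(strata):
            rows.append(row(str(name), strata == name))
    rows.append(row("Total", np.ones(labels.size, dtype=bool)))
    return pd.DataFrame(rows)
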