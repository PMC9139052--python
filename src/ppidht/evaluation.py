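"""Confusion-matrix metrics, ROC/AUC, and five-fold cross-validation.

Metrics follow the standard binary-classification definitions with class 1 =
interacting pair:

    ACC  = (TP + TN) / (TP + FP + TN + FN)
    Sen  = TP / (TP + FN)
    Spec = TN / (TN + FP)
    PR   = TP / (TP + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Any 0/0 ratio is reported as NaN (an explicit undefined marker), never
silently 0.  AUC is computed by the midrank method — the probability that a
random positive outscores a random negative — and equals trapezoidal
integration of the ROC curve.

Cross-validation is stratified k-fold (default k=5): each sample is tested
exactly once, and the report carries per-fold metrics plus mean and sample
standard deviation, in the layout conventional for PPI benchmarks
("Average  91.93 ± 0.69").  Ratio metrics are reported as percentages; MCC
is additionally printed on the x100 convention; AUC stays a fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .rotation_forest import RotationForestClassifier

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "roc_auc",
    "kfold_cv",
    "EvaluationReport",
]

METRIC_NAMES = ("ACC", "Sen", "Spec", "PR", "MCC", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts for a binary task (class 1 = interacting)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Cross-tabulate binary truth against binary predictions."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"length mismatch: {y_true.shape} truth vs {y_pred.shape} predictions"
        )
    if y_true.size < 1:
        raise ValueError("need at least one sample")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision (each in [0, 1]) and
    MCC (in [-1, 1]) from confusion counts; NaN marks undefined ratios."""
    if c.total < 1:
        raise ValueError("empty confusion table")
    mcc_den = (
        (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return {
        "ACC": _ratio(c.tp + c.tn, c.total),
        "Sen": _ratio(c.tp, c.tp + c.fn),
        "Spec": _ratio(c.tn, c.tn + c.fp),
        "PR": _ratio(c.tp, c.tp + c.fp),
        "MCC": (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den)
        if mcc_den > 0
        else math.nan,
    }


def roc_auc(y_true, scores):
    """AUC by midrank statistics plus the ROC point list.

    Returns ``(auc, points)`` where ``points`` is an (m, 2) array of
    (FPR, TPR) pairs.  The AUC equals the probability that a uniformly random
    positive receives a higher score than a uniformly random negative, with
    ties counted half.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape or y_true.ndim != 1:
        raise ValueError("y_true and scores must be 1-D of equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # midranks for ties
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # ROC points: sweep thresholds from +inf downward over distinct scores.
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tps = np.cumsum(y_true[order] == 1)
    fps = np.cumsum(y_true[order] == 0)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    points = np.column_stack(
        [np.r_[0.0, fps[distinct] / n_neg], np.r_[0.0, tps[distinct] / n_pos]]
    )
    return float(auc), points


@dataclass
class EvaluationReport:
    """Per-fold metrics with a mean ± sd summary row.

    ``folds`` holds one dict per fold with ACC/Sen/Spec/PR as percentages,
    MCC as a percentage (x100 convention), MCC_frac on [-1, 1], and AUC as a
    fraction.  ``roc_points`` holds each fold's ROC curve.
    """

    folds: List[dict]
    roc_points: List[np.ndarray] = field(default_factory=list)
    seed: Optional[int] = None

    def _values(self, name: str) -> np.ndarray:
        return np.array([f[name] for f in self.folds], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self._values(name)))

    def sd(self, name: str) -> float:
        """Sample standard deviation (n-1 denominator) across folds."""
        vals = self._values(name)
        return float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict:
        return {
            name: (self.mean(name), self.sd(name))
            for name in METRIC_NAMES
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds, start=1):
            rows.append({"Fold": str(i), **{n: f[n] for n in METRIC_NAMES}})
        df = pd.DataFrame(rows)
        return df

    def to_table(self) -> str:
        """Delimited table: one row per fold plus an Average 'mean ± sd' row."""
        lines = ["Fold\t" + "\t".join(METRIC_NAMES)]
        for i, f in enumerate(self.folds, start=1):
            cells = [f"{f[n]:.4f}" if n == "AUC" else f"{f[n]:.2f}" for n in METRIC_NAMES]
            lines.append(f"{i}\t" + "\t".join(cells))
        cells = []
        for n in METRIC_NAMES:
            if n == "AUC":
                cells.append(f"{self.mean(n):.4f} ± {self.sd(n):.4f}")
            else:
                cells.append(f"{self.mean(n):.2f} ± {self.sd(n):.2f}")
        lines.append("Average\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def _fold_metrics(y_true, y_pred, scores) -> dict:
    m = metrics(confusion(y_true, y_pred))
    auc, points = roc_auc(y_true, scores)
    return (
        {
            "ACC": 100.0 * m["ACC"],
            "Sen": 100.0 * m["Sen"],
            "Spec": 100.0 * m["Spec"],
            "PR": 100.0 * m["PR"],
            "MCC": 100.0 * m["MCC"],
            "MCC_frac": m["MCC"],
            "AUC": auc,
        },
        points,
    )


def kfold_cv(
    X,
    y,
    k: int = 5,
    n_estimators: int = 30,
    n_subsets: int = 20,
    bootstrap_frac: float = 0.75,
    random_state: Optional[int] = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the rotation forest.

    Samples are split into k stratified folds (so both classes appear in
    every training split of a balanced design); each fold is held out once,
    a fresh classifier is fitted on the rest, and fold metrics are collected.
    One seed controls fold assignment, and per-fold model seeds are derived
    from it, so a fixed seed reproduces the report exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(X) < k:
        raise ValueError(f"need at least k={k} samples, got {len(X)}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    seed_seq = np.random.SeedSequence(random_state)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seed_seq.spawn(k)]
    folds, rocs = [], []
    for fold_seed, (train_idx, test_idx) in zip(fold_seeds, splitter.split(X, y)):
        clf = RotationForestClassifier(
            n_estimators=n_estimators,
            n_subsets=n_subsets,
            bootstrap_frac=bootstrap_frac,
            random_state=fold_seed,
        ).fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, list(clf.classes_).index(1)]
        y_pred = clf.predict(X[test_idx])
        fold, points = _fold_metrics(y[test_idx], y_pred, scores)
        folds.append(fold)
        rocs.append(points)
    return EvaluationReport(folds=folds, roc_points=rocs, seed=random_state)
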