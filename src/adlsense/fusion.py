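"""Reliability-weighted decision fusion and the evaluation harness.

The three sensing groups emit per-window class scores: G1's clinical
threshold count mapped to a probability, and the G2/G3 HMM posteriors.
Each group j earns a per-class precision p_ij (true positives over
predicted positives of its hard argmax predictions), estimated by
stratified k-fold cross-validation; normalising over the classes within a
group gives its reliability score

    Rs_ij = p_ij / sum_i p_ij

and the fused decision is the class maximising the reliability-weighted
sum of group scores:

    d(x) = argmax_i  sum_j Rs_ij * P_j(i)

Ties resolve toward "normal", biasing against false alarms.  The harness
reports ROC/AUC and precision/recall/F1 via scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (precision_recall_fscore_support, roc_auc_score,
                             roc_curve)
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CLASSES",
    "group_precision",
    "reliability_scores",
    "crossval_reliability",
    "fuse",
    "FusionResult",
    "ReliabilityFusion",
    "roc_auc",
    "classification_report_frame",
]

CLASSES = ("normal", "AIA")  # "normal" first: argmax ties fall back to it
GROUPS = ("G1", "G2", "G3")


def _hard_labels(p_aia: np.ndarray) -> np.ndarray:
    """Argmax class of a (P(AIA), P(normal)) score; ties go to normal."""
    return np.where(np.asarray(p_aia) > 0.5, "AIA", "normal").astype(object)


def group_precision(
    predictions: Sequence[str], truth: Sequence[str]
) -> dict[str, float]:
    """Per-class precision p_i = TP_i / (TP_i + FP_i) of one group's argmax
    predictions; a class the group never predicts gets precision 0 with a
    warning."""
    pred = np.asarray(predictions, dtype=object)
    true = np.asarray(truth, dtype=object)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("need aligned, non-empty prediction and truth vectors")
    out = {}
    for cls in CLASSES:
        predicted = pred == cls
        if not predicted.any():
            warnings.warn(f"no predictions for class {cls!r}; precision set to 0",
                          stacklevel=2)
            out[cls] = 0.0
        else:
            out[cls] = float((true[predicted] == cls).mean())
    return out


def reliability_scores(
    precisions: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Normalise per-group class precisions into reliability weights.

    Returns a (classes x groups) DataFrame whose columns each sum to 1; a
    group with all-zero precisions gets a uniform column with a warning.
    """
    rs = {}
    for group, p in precisions.items():
        col = np.asarray([p[c] for c in CLASSES], dtype=float)
        total = col.sum()
        if total <= 0:
            warnings.warn(f"group {group!r} has all-zero precisions; "
                          "using uniform reliability", stacklevel=2)
            col = np.full(len(CLASSES), 1.0 / len(CLASSES))
        else:
            col = col / total
        rs[group] = col
    return pd.DataFrame(rs, index=list(CLASSES))


def crossval_reliability(
    scores: pd.DataFrame,
    truth: Sequence[str],
    k: int = 10,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Reliability matrix from stratified k-fold cross-validation.

    `scores` holds one column of P(AIA) per group over labelled windows.
    Per fold, each group's per-class precision is computed on the held-out
    windows; precisions are averaged over folds and then normalised into
    reliability weights.  If the rarer class has fewer than k members, k is
    reduced (with a warning) so every fold contains both classes.
    """
    truth = np.asarray(truth, dtype=object)
    if len(scores) != len(truth):
        raise ValueError("scores and truth must be aligned")
    class_counts = pd.Series(truth).value_counts()
    if len(class_counts) < 2:
        raise ValueError("both classes must be present to learn reliabilities")
    k_eff = int(min(k, class_counts.min()))
    if k_eff < k:
        warnings.warn(f"reducing folds from {k} to {k_eff} so each fold keeps "
                      "both classes", stacklevel=2)
    if k_eff < 2:
        raise ValueError("need at least 2 windows of the rarer class")

    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    sums = {g: np.zeros(len(CLASSES)) for g in scores.columns}
    for _train, test in skf.split(scores, truth):
        for group in scores.columns:
            pred = _hard_labels(scores[group].to_numpy()[test])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty-prediction classes -> 0
                p = group_precision(pred, truth[test])
            sums[group] += [p[c] for c in CLASSES]
    mean_p = {g: {c: s[i] / k_eff for i, c in enumerate(CLASSES)}
              for g, s in sums.items()}
    return reliability_scores(mean_p)


@dataclass
class FusionResult:
    """Fused decision for one window."""

    class_scores: dict[str, float]
    label: str
    contributing: dict[str, tuple[float, float]]


def fuse(
    group_scores: Mapping[str, tuple[float, float]],
    reliability: pd.DataFrame,
) -> FusionResult:
    """Reliability-weighted vote over the available groups.

    `group_scores` maps each group to its (P(AIA), P(normal)) pair; a
    missing group's term is simply omitted (and the caller warned), since
    e.g. twice-daily vitals are frequently skipped in practice.  The label
    is the argmax class, ties toward "normal".
    """
    present = [g for g in reliability.columns if g in group_scores]
    if not present:
        raise ValueError("no group scores available to fuse")
    if len(present) < len(reliability.columns):
        warnings.warn(
            f"missing group(s) {sorted(set(reliability.columns) - set(present))}; "
            "fusing the remaining groups", stacklevel=2)
    class_scores = {}
    for cls in CLASSES:
        total = 0.0
        for g in present:
            p_aia, p_normal = group_scores[g]
            p_cls = p_aia if cls == "AIA" else p_normal
            total += float(reliability.loc[cls, g]) * p_cls
        class_scores[cls] = total
    label = max(CLASSES, key=lambda c: (class_scores[c], c == "normal"))
    return FusionResult(class_scores, label, dict(group_scores))


class ReliabilityFusion(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper: learn Rs by cross-validation, then fuse.

    `X` is an (n_windows, n_groups) array of per-group P(AIA) scores
    (column order = `groups`), `y` the window labels in {"normal", "AIA"}.
    """

    def __init__(self, groups: Sequence[str] = GROUPS, k: int = 10,
                 random_state: int | None = 0):
        self.groups = tuple(groups)
        self.k = k
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "ReliabilityFusion":
        X = np.asarray(X, dtype=float)
        scores = pd.DataFrame(X, columns=list(self.groups))
        self.reliability_ = crossval_reliability(
            scores, y, k=self.k, seed=self.random_state)
        self.classes_ = np.asarray(CLASSES, dtype=object)
        return self

    def decision_scores(self, X: np.ndarray) -> pd.DataFrame:
        """Fused per-class scores, one row per window (columns = classes)."""
        X = np.asarray(X, dtype=float)
        rows = []
        for row in X:
            scores = {g: (p, 1.0 - p) for g, p in zip(self.groups, row)}
            rows.append(fuse(scores, self.reliability_).class_scores)
        return pd.DataFrame(rows, columns=list(CLASSES))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Fused class scores normalised to probabilities (columns = classes_)."""
        scores = self.decision_scores(X).to_numpy()
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        # argmax with ties toward "normal" (column order puts normal first)
        return scores.columns.to_numpy(dtype=object)[
            scores.to_numpy().argmax(axis=1)]


def roc_auc(
    scores: Sequence[float], truth: Sequence[str]
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and ROC points for P(AIA)-style scores against window labels."""
    y = (np.asarray(truth, dtype=object) == "AIA").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute an ROC curve")
    fpr, tpr, _ = roc_curve(y, scores)
    return float(roc_auc_score(y, scores)), fpr, tpr


def classification_report_frame(
    predictions: Sequence[str], truth: Sequence[str]
) -> dict:
    """Per-class precision/recall/F1 plus support-weighted averages."""
    pred = np.asarray(predictions, dtype=object)
    true = np.asarray(truth, dtype=object)
    per_class = {}
    p, r, f, s = precision_recall_fscore_support(
        true, pred, labels=list(CLASSES), zero_division=0)
    for i, cls in enumerate(CLASSES):
        per_class[cls] = {"precision": float(p[i]), "recall": float(r[i]),
                          "f1": float(f[i]), "support": int(s[i])}
    wp, wr, wf, _ = precision_recall_fscore_support(
        true, pred, labels=list(CLASSES), average="weighted", zero_division=0)
    return {"per_class": per_class,
            "weighted": {"precision": float(wp), "recall": float(wr),
                         "f1": float(wf)}}
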