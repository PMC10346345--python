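"""Stratified k-fold evaluation with the full metric panel.

Three labelings of the four walking conditions are evaluated: the
four-class problem (NW / STROOP / COM / MLP), a three-class problem that
drops the perturbation trials (NW / STROOP / COM), and the two-class
stable-vs-unstable grouping (stable = NW + COM, unstable = STROOP + MLP).

Metrics per model: accuracy, macro precision/recall/F-score, multiclass
Matthews correlation (covariance form), macro one-vs-rest ROC AUC, a
pooled confusion matrix and per-class ROC curves.  Fold averages are
weighted by fold size, so the reported accuracy equals
trace(confusion) / total exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (confusion_matrix, f1_score, matthews_corrcoef,
                             precision_score, recall_score, roc_auc_score,
                             roc_curve)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import models as _models
from .models import ModelSpec
from .synth import CONDITIONS, STABLE_CONDITIONS

__all__ = ["EvaluationReport", "make_labels", "compute_metrics",
           "crossvalidate", "LABELINGS"]

LABELINGS = ("four_class", "three_class", "two_class")


def make_labels(conditions: np.ndarray,
                labeling: str) -> tuple[np.ndarray, np.ndarray]:
    """Map per-cycle conditions to class labels under a labeling scheme.

    Returns ``(mask, labels)``: ``mask`` marks the cycles retained (the
    three-class scheme drops MLP), ``labels`` are the class labels of the
    retained cycles.
    """
    conditions = np.asarray(conditions)
    unknown = set(np.unique(conditions)) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition(s): {sorted(unknown)}")
    if labeling == "four_class":
        return np.ones(len(conditions), dtype=bool), conditions.copy()
    if labeling == "three_class":
        mask = conditions != "MLP"
        if not mask.any():
            warnings.warn("three_class labeling on MLP-only input is empty",
                          RuntimeWarning)
        return mask, conditions[mask]
    if labeling == "two_class":
        labels = np.where(np.isin(conditions, sorted(STABLE_CONDITIONS)),
                          "stable", "unstable")
        return np.ones(len(conditions), dtype=bool), labels
    raise ValueError(f"unknown labeling {labeling!r}")


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray | None = None,
                    class_order: np.ndarray | None = None) -> dict:
    """Accuracy, macro precision/recall/F1, MCC and macro one-vs-rest AUC.

    ``scores`` columns follow ``class_order``.  Classes absent from
    ``y_true`` are excluded from the macro averages with a warning.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if class_order is None:
        class_order = np.unique(np.concatenate([y_true, y_pred]))
    present = np.unique(y_true)
    if len(present) < len(class_order):
        missing = sorted(set(class_order) - set(present))
        warnings.warn(f"class(es) {missing} absent from y_true; excluded "
                      "from macro averages", RuntimeWarning)
    out = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision": float(precision_score(
            y_true, y_pred, labels=present, average="macro",
            zero_division=0)),
        "recall": float(recall_score(
            y_true, y_pred, labels=present, average="macro",
            zero_division=0)),
        "f_score": float(f1_score(
            y_true, y_pred, labels=present, average="macro",
            zero_division=0)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
    }
    if scores is not None:
        auc = _macro_ovr_auc(y_true, scores, class_order)
        out["roc_area"] = auc
        out["auc"] = auc
    return out


def _macro_ovr_auc(y_true: np.ndarray, scores: np.ndarray,
                   class_order: np.ndarray) -> float:
    aucs = []
    for j, cls in enumerate(class_order):
        pos = y_true == cls
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos.astype(int), scores[:, j]))
    return float(np.mean(aucs)) if aucs else float("nan")


@dataclass
class EvaluationReport:
    """Cross-validated performance of one model under one labeling."""

    labeling: str
    model_kind: str
    metrics: dict
    per_fold: list[dict]
    confusion: list[list[int]]
    class_order: list[str]
    roc_curves: dict[str, dict]
    fold_sizes: list[int]
    seed: int
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "labeling": self.labeling,
            "model_kind": self.model_kind,
            "metrics": self.metrics,
            "per_fold": self.per_fold,
            "confusion": self.confusion,
            "class_order": list(map(str, self.class_order)),
            "roc_curves": self.roc_curves,
            "fold_sizes": self.fold_sizes,
            "seed": self.seed,
            "n_samples": self.n_samples,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def crossvalidate(X, y, spec: ModelSpec, k: int = 5, seed: int = 0,
                  groups: np.ndarray | None = None,
                  feature_names: list[str] | None = None,
                  per_fold_selection: dict | None = None,
                  labeling: str = "") -> EvaluationReport:
    """Stratified k-fold cross-validation of one model.

    ``X`` is a feature matrix (2-D) or cycle tensor (3-D) matching the
    model's input contract.  With ``groups`` (subject ids) folds are
    subject-wise (leakage-free); default is cycle-wise stratification.
    ``per_fold_selection`` = {"k": ..., "corr_threshold": ...} re-runs
    feature selection inside every training fold.
    """
    from .io_formats import FeatureTable
    if isinstance(X, FeatureTable):
        feature_names = feature_names or X.feature_names
        Xarr = X.values
    else:
        Xarr = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    class_order, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class {class_order[np.argmin(counts)]!r} has fewer than "
            f"k={k} samples")
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        split = splitter.split(np.zeros(len(y)), y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y)

    n = len(y)
    pooled_pred = np.empty(n, dtype=object)
    pooled_scores = np.zeros((n, len(class_order)))
    per_fold, fold_sizes = [], []
    for fold, (tr, te) in enumerate(split):
        Xtr, Xte = Xarr[tr], Xarr[te]
        if per_fold_selection is not None:
            if feature_names is None or Xarr.ndim != 2:
                raise ValueError("per-fold selection needs a 2-D feature "
                                 "matrix and feature names")
            import pandas as pd
            frame = pd.DataFrame(Xtr, columns=feature_names)
            frame.insert(0, "cycle_index", np.arange(len(tr)))
            frame.insert(0, "condition", y[tr])
            frame.insert(0, "subject", 0)
            from .selection import select_features
            sel = select_features(FeatureTable(frame), y[tr],
                                  k=per_fold_selection.get("k", 40),
                                  corr_threshold=per_fold_selection.get(
                                      "corr_threshold", 0.8))
            cols = [feature_names.index(f) for f in sel.selected]
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
        fold_spec = ModelSpec(spec.kind, dict(spec.hyperparameters),
                              seed=(seed * 1000 + fold) % (2**31 - 1),
                              n_classes=spec.n_classes)
        fitted = _models.train(fold_spec, Xtr, y[tr])
        pred, scores = _models.predict(fitted, Xte)
        # align score columns with the global class order
        col = {c: j for j, c in enumerate(fitted.classes_)}
        for j, cls in enumerate(class_order):
            if cls in col:
                pooled_scores[te, j] = scores[:, col[cls]]
        pooled_pred[te] = pred
        fold_metrics = compute_metrics(y[te], pred, pooled_scores[te],
                                       class_order)
        fold_metrics["fold"] = fold
        per_fold.append(fold_metrics)
        fold_sizes.append(len(te))

    pooled_pred = pooled_pred.astype(class_order.dtype)
    weights = np.asarray(fold_sizes, dtype=float)
    weights /= weights.sum()
    metric_names = [m for m in per_fold[0] if m != "fold"]
    metrics = {m: float(np.sum(weights * np.array([f[m] for f in per_fold])))
               for m in metric_names}
    conf = confusion_matrix(y, pooled_pred, labels=class_order)
    curves = {}
    for j, cls in enumerate(class_order):
        pos = (y == cls).astype(int)
        if 0 < pos.sum() < n:
            fpr, tpr, _ = roc_curve(pos, pooled_scores[:, j])
            curves[str(cls)] = {"fpr": [round(float(v), 6) for v in fpr],
                                "tpr": [round(float(v), 6) for v in tpr]}
    return EvaluationReport(
        labeling=labeling, model_kind=spec.kind, metrics=metrics,
        per_fold=per_fold, confusion=conf.tolist(),
        class_order=[str(c) for c in class_order], roc_curves=curves,
        fold_sizes=fold_sizes, seed=seed, n_samples=n)
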