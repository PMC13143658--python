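"""Classification metrics, cross-validation, and the ablation harness.

Precision and recall follow the per-class TP/(TP+FP) and TP/(TP+FN)
definitions on a percent scale, macro-averaged for multiclass problems; ROC
AUC is the rank statistic (probability a random positive outscores a random
negative, ties at mid-rank), averaged one-vs-rest for k > 2.  Cross-validation
is stratified and leakage-free: normalization, feature selection and model
fitting all happen inside each training fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ConfigurationError, InvalidInputError
from .efmlnp import ensemble_predict, train_efmlnp
from .rsso import run_rsso

__all__ = [
    "EvaluationReport",
    "confusion_and_metrics",
    "roc_auc",
    "kfold_cross_validate",
    "ablation_study",
]


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    classes: list
    accuracy: float  # percent
    precision: float  # percent, macro
    recall: float  # percent, macro
    f1: float  # percent, macro
    roc_auc: float | None = None
    per_class: dict = field(default_factory=dict)
    folds: list | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "per_class": self.per_class,
            "config": self.config,
            "seed": self.seed,
        }
        if self.folds is not None:
            d["folds"] = self.folds
        return d

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def confusion_and_metrics(y_true, y_pred, classes=None, scores=None, seed=None) -> EvaluationReport:
    """Confusion matrix plus percent-scale accuracy/precision/recall/F1.

    Per class c: precision = TP/(TP+FP)*100, recall = TP/(TP+FN)*100,
    F1 = 2PR/(P+R); the headline numbers are macro averages.  Classes with a
    zero denominator score 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise InvalidInputError("label sequences must be equal-length and non-empty")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    cm = _sk_confusion(y_true, y_pred, labels=classes)

    per_class = {}
    precisions, recalls, f1s = [], [], []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0 or tp + fn == 0:
            warnings.warn(f"class {c!r}: zero denominator, metric set to 0")
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        per_class[str(c)] = {"tp": int(tp), "fp": int(fp), "fn": int(fn),
                             "precision": p, "recall": r, "f1": f}
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)

    auc = None
    if scores is not None:
        auc = roc_auc(scores, y_true, classes=classes)
    return EvaluationReport(
        confusion=cm,
        classes=list(classes),
        accuracy=100.0 * np.trace(cm) / cm.sum(),
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        roc_auc=auc,
        per_class=per_class,
        seed=seed,
    )


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("ROC AUC needs both classes present")
    ranks = rankdata(scores)  # mid-ranks on ties
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(scores, y_true, classes=None) -> float:
    """Rank-statistic AUC; unweighted mean of one-vs-rest AUCs for k > 2."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise InvalidInputError("ROC AUC needs both classes present")
    if scores.ndim == 1:
        if classes is None:
            classes = sorted(np.unique(y_true).tolist())
        if len(classes) != 2:
            raise InvalidInputError("1-D scores require a binary problem")
        return _binary_auc(scores, y_true == classes[1])
    if classes is None:
        classes = sorted(np.unique(y_true).tolist())
    aucs = []
    for i, c in enumerate(classes):
        positive = y_true == c
        if positive.any() and (~positive).any():
            aucs.append(_binary_auc(scores[:, i], positive))
    return float(np.mean(aucs))


def _fit_predict(X_tr, y_tr, X_te, cfg: dict, seed: int):
    """Train the configured pipeline on one fold and score the held-out part."""
    selected = None
    if cfg.get("use_selection", False):
        sel = run_rsso(X_tr, y_tr, seed=seed, **cfg.get("selection", {}))
        selected = sel.selected
        X_tr, X_te = X_tr[:, selected], X_te[:, selected]
    model = train_efmlnp(X_tr, y_tr, seed=seed, **cfg.get("model", {}))
    labels, scores = ensemble_predict(model, X_te)
    return labels, scores, selected, model


def kfold_cross_validate(X, y, k: int = 5, seed: int = 0, cfg: dict | None = None) -> EvaluationReport:
    """Stratified k-fold cross-validation of the selection + ensemble pipeline.

    Folds differ in size by at most one; every sample is validated exactly
    once; feature selection and all normalization are refit inside each
    training fold.  The report carries per-fold metrics and their mean/sd.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cfg = cfg or {}
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise InvalidInputError(f"every class needs >= {k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    fold_reports = []
    all_true, all_pred = [], []
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        labels, _, selected, _ = _fit_predict(X[tr], y[tr], X[te], cfg, seed=seed + fold_idx)
        rep = confusion_and_metrics(y[te], labels)
        fold_reports.append(
            {
                "fold": fold_idx,
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
                "selected": selected,
            }
        )
        all_true.append(y[te])
        all_pred.append(labels)

    overall = confusion_and_metrics(np.concatenate(all_true), np.concatenate(all_pred))
    overall.folds = fold_reports
    overall.seed = seed
    means = {m: float(np.mean([f[m] for f in fold_reports])) for m in ("accuracy", "precision", "recall", "f1")}
    sds = {m: float(np.std([f[m] for f in fold_reports])) for m in ("accuracy", "precision", "recall", "f1")}
    overall.config = {"k": k, "fold_mean": means, "fold_sd": sds, **cfg}
    return overall


def ablation_study(
    mri_X, ecg_X, y, seed: int = 0, test_size: float = 0.3, cfg: dict | None = None
) -> pd.DataFrame:
    """Four-configuration ablation on one shared stratified train/test split:
    MRI-only, ECG-only, fused without selection, and the full framework with
    spider-swarm selection.  Returns a 4-row metrics table."""
    cfg = cfg or {}
    mri_X = np.asarray(mri_X, dtype=float)
    ecg_X = np.asarray(ecg_X, dtype=float)
    y = np.asarray(y)
    if mri_X.ndim != 2 or ecg_X.ndim != 2 or not (mri_X.shape[0] == ecg_X.shape[0] == y.shape[0]):
        raise ConfigurationError("ablation needs paired MRI and ECG feature tables with shared labels")

    fused = np.hstack([mri_X, ecg_X])
    idx = np.arange(y.size)
    tr, te = train_test_split(idx, test_size=test_size, stratify=y, random_state=seed)

    rows = []
    for name, block, use_sel in (
        ("mri_only", mri_X, False),
        ("ecg_only", ecg_X, False),
        ("fusion_no_selection", fused, False),
        ("full_framework", fused, True),
    ):
        run_cfg = dict(cfg)
        run_cfg["use_selection"] = use_sel
        labels, scores, selected, _ = _fit_predict(block[tr], y[tr], block[te], run_cfg, seed=seed)
        rep = confusion_and_metrics(y[te], labels, scores=scores)
        rows.append(
            {
                "configuration": name,
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
                "roc_auc": rep.roc_auc,
                "selected_features": "" if selected is None else ",".join(map(str, selected)),
            }
        )
    return pd.DataFrame(rows)
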