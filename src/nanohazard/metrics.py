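"""Validation metric suite shared by the QSAR baselines and the
Bayesian network: MAE/RMSE/R2 for regression, and one-vs-rest
per-class precision, recall, F1 and balanced accuracy plus the
multiclass Matthews correlation coefficient for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, matthews_corrcoef


@dataclass
class MetricsReport:
    """Container for one model's validation metrics."""

    regression: dict[str, float] = field(default_factory=dict)
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    balanced_accuracy: float = float("nan")
    mcc: float = float("nan")
    confusion: pd.DataFrame | None = None
    n: int = 0

    def to_dict(self) -> dict:
        out = {"n": self.n}
        if self.regression:
            out["regression"] = self.regression
        if self.per_class:
            out["per_class"] = self.per_class
            out["balanced_accuracy"] = self.balanced_accuracy
            out["mcc"] = self.mcc
            out["confusion"] = self.confusion.to_dict()
        return out


def regression_metrics(y: Sequence[float], yhat: Sequence[float]) -> tuple[float, float, float]:
    """(MAE, RMSE, R2); R2 is NaN when y is constant and may be
    negative on test data (reported as computed)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or len(y) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(err**2)) / ss_tot
    return mae, rmse, r2


def classification_metrics(
    y: Sequence, yhat: Sequence, classes: Sequence[str] | None = None
) -> MetricsReport:
    """One-vs-rest per-class metrics and multiclass MCC.

    Per class c: precision, recall (TPR), F1, and balanced accuracy
    (TPR_c + TNR_c)/2.  The overall balanced accuracy is the macro
    mean of per-class recalls.  A class with zero support and zero
    predictions is reported as NaN and excluded from macro means.
    """
    y = pd.Series(list(y)).astype(str)
    yhat = pd.Series(list(yhat)).astype(str)
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    labels = list(classes) if classes is not None else sorted(set(y) | set(yhat))
    cm = confusion_matrix(y, yhat, labels=labels)
    n = cm.sum()
    per_class: dict[str, dict[str, float]] = {}
    recalls = []
    for i, c in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0 and tp + fp == 0:
            per_class[c] = {k: float("nan") for k in
                            ("precision", "recall", "f1", "balanced_accuracy", "support")}
            per_class[c]["support"] = 0.0
            continue
        prec = tp / (tp + fp) if tp + fp > 0 else float("nan")
        rec = tp / (tp + fn) if tp + fn > 0 else float("nan")
        tnr = tn / (tn + fp) if tn + fp > 0 else float("nan")
        f1 = (2 * prec * rec / (prec + rec)) if prec + rec > 0 else 0.0
        per_class[c] = {
            "precision": float(prec),
            "recall": float(rec),
            "f1": float(f1),
            "balanced_accuracy": float((rec + tnr) / 2.0),
            "support": float(tp + fn),
        }
        if tp + fn > 0:
            recalls.append(rec)
    mcc = float(matthews_corrcoef(y, yhat)) if len(set(y)) > 1 or len(set(yhat)) > 1 else 1.0
    return MetricsReport(
        per_class=per_class,
        balanced_accuracy=float(np.mean(recalls)) if recalls else float("nan"),
        mcc=mcc,
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        n=int(n),
    )
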