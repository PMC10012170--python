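"""QSAR baseline sweep: a representative set of tree-ensemble and
linear learners on the preprocessed table, as regression on viability
and classification on the hazard class, with 10-fold internal
cross-validation and an external 20 % test split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, train_test_split

from .metrics import MetricsReport, classification_metrics, regression_metrics
from .preprocessing import smote_oversample
from .schema import Dataset


@dataclass
class SplitSpec:
    """Train/test split specification (default 80/20)."""

    train_fraction: float = 0.8
    stratify: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train fraction must be in (0, 1)")


def split_dataset(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive train/test split, stratified by the hazard
    class when flagged; deterministic given the seed."""
    df = dataset.frame
    if len(df) < 10:
        raise ValueError("dataset too small to split")
    strat = None
    if spec.stratify:
        out_cols = dataset.columns_with_role("output")
        if out_cols:
            strat = df[out_cols[0]]
    idx_train, idx_test = train_test_split(
        np.arange(len(df)),
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    tr = Dataset(df.iloc[np.sort(idx_train)].reset_index(drop=True), dict(dataset.roles))
    te = Dataset(df.iloc[np.sort(idx_test)].reset_index(drop=True), dict(dataset.roles))
    return tr, te


def default_regressors(seed: int = 0) -> dict[str, object]:
    return {
        "rfr": RandomForestRegressor(random_state=seed, n_jobs=1),
        "etr": ExtraTreesRegressor(random_state=seed, n_jobs=1),
        "lightgbm": LGBMRegressor(random_state=seed, verbose=-1, n_jobs=1),
        "linear": LinearRegression(),
    }


def default_classifiers(seed: int = 0) -> dict[str, object]:
    return {
        "rf": RandomForestClassifier(random_state=seed, n_jobs=1),
        "et": ExtraTreesClassifier(random_state=seed, n_jobs=1),
        "lightgbm": LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1),
        "logistic": LogisticRegression(max_iter=2000),
    }


def _check_finite(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")


def _cv_scores_regression(model, X, y, n_folds, seed):
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    maes = []
    for tr, va in kf.split(X):
        m = type(model)(**model.get_params())
        m.fit(X[tr], y[tr])
        mae, _, _ = regression_metrics(y[va], m.predict(X[va]))
        maes.append(mae)
    return float(np.mean(maes))


def fit_regressors(
    train_X: pd.DataFrame,
    train_y: Sequence[float],
    test_X: pd.DataFrame,
    test_y: Sequence[float],
    models: Mapping[str, object] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Fit the regressor set on viability %, report internal 10-fold
    CV MAE on the training split and external MAE/RMSE/R2 on test."""
    models = models or default_regressors(seed)
    Xtr = np.asarray(train_X, dtype=float)
    Xte = np.asarray(test_X, dtype=float)
    _check_finite(Xtr), _check_finite(Xte)
    ytr = np.asarray(train_y, dtype=float)
    yte = np.asarray(test_y, dtype=float)
    reports = {}
    for name, model in models.items():
        cv_mae = _cv_scores_regression(model, Xtr, ytr, n_folds, seed)
        model.fit(Xtr, ytr)
        mae, rmse, r2 = regression_metrics(yte, model.predict(Xte))
        reports[name] = MetricsReport(
            regression={"mae": mae, "rmse": rmse, "r2": r2, "cv_mae": cv_mae},
            n=len(yte),
        )
    return reports


def fit_classifiers(
    train_X: pd.DataFrame,
    train_y: Sequence,
    test_X: pd.DataFrame,
    test_y: Sequence,
    models: Mapping[str, object] | None = None,
    smote: bool = True,
    smote_seed: int = 0,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Fit the classifier set on the hazard class.

    SMOTE balancing is applied to the training split only; the test
    split stays untouched.
    """
    models = models or default_classifiers(seed)
    Xtr = pd.DataFrame(train_X).reset_index(drop=True)
    ytr = pd.Series(list(train_y)).reset_index(drop=True)
    if smote:
        Xtr, ytr = smote_oversample(Xtr, ytr, seed=smote_seed)
    _check_finite(np.asarray(Xtr, dtype=float))
    _check_finite(np.asarray(test_X, dtype=float))
    classes = sorted(set(map(str, train_y)))
    reports = {}
    for name, model in models.items():
        model.fit(np.asarray(Xtr, dtype=float), ytr.astype(str))
        yhat = model.predict(np.asarray(test_X, dtype=float))
        reports[name] = classification_metrics(list(map(str, test_y)), yhat, classes=classes)
    return reports


def leaderboard(reports: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """Flat model x metric table mirroring a results leaderboard."""
    rows = []
    for name, rep in reports.items():
        row: dict[str, object] = {"model": name}
        row.update(rep.regression)
        if rep.per_class:
            row["balanced_accuracy"] = rep.balanced_accuracy
            row["mcc"] = rep.mcc
            for c, m in rep.per_class.items():
                row[f"f1_{c}"] = m["f1"]
        rows.append(row)
    return pd.DataFrame(rows)
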