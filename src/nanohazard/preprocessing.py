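"""Dataset preparation: strata-wise interpolation, chained imputation,
feature finalization, one-hot encoding, SMOTE balancing, and tercile
quantile discretization.

The order of the full chain is: dose-wise linear interpolation of the
DLS columns within (nanoform, cell line, pretreatment) strata, chained
gradient-boosted-regression imputation of what remains, reduction to
the final modeling feature set, hazard-class discretization of the
outcome, and either one-hot + SMOTE (for the numeric learners) or
tercile binning (for the Bayesian network).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.neighbors import NearestNeighbors

from .schema import (
    CATEGORICAL_INPUTS,
    Dataset,
    HazardClass,
    NUMERIC_INPUTS,
    SYSTEM_DEPENDENT,
    classify_viability_series,
)

__all__ = [
    "FINAL_NUMERIC",
    "FINAL_CATEGORICAL",
    "DiscretizationMap",
    "BinnedDataset",
    "OneHotMap",
    "interpolate_strata",
    "iterative_impute",
    "finalize_features",
    "smote_oversample",
    "fit_quantile_bins",
    "apply_bins",
]

#: Strata within which dose-wise interpolation is allowed.
STRATA_KEY = ["erm_id", "cell_line", "pretreatment"]

#: Final modeling features (15 inputs + hazard outcome).
FINAL_NUMERIC = [
    "o1s_at", "ag3d_at", "c1s_at", "core_size", "spherical_surface_area",
    "crystallinity", "avg_crystallite_size", "hydro_size_t0", "hydro_size_t24",
    "pdi_t0", "pdi_t24", "dose",
]
FINAL_CATEGORICAL = ["coating", "cell_line", "assay"]
DROPPED_ON_FINALIZE = [
    "organ", "multiwell", "cell_type", "na1s_at", "n1s_at", "duration",
    "erm_id", "pretreatment", "viability",
]

BIN_LABELS = ("low", "medium", "high")


def interpolate_strata(
    dataset: Dataset, columns: Sequence[str] | None = None
) -> Dataset:
    """Fill missing system-dependent values by dose-wise linear
    interpolation within (nanoform, cell line, pretreatment) strata.

    A missing value at dose d is interpolated between the nearest known
    smaller and larger doses of the same stratum; values outside the
    known dose range stay missing, and values never cross strata.
    Observed cells are never altered.
    """
    columns = list(columns) if columns is not None else list(SYSTEM_DEPENDENT)
    out = dataset.copy()
    df = out.frame
    for _, idx in df.groupby(STRATA_KEY, dropna=False, observed=True).groups.items():
        sub = df.loc[idx]
        for col in columns:
            observed = sub[sub[col].notna()]
            if len(observed) < 1:
                continue
            # average observed values per dose (replicates share a dose)
            per_dose = observed.groupby("dose")[col].mean()
            if len(per_dose) < 2:
                continue
            xs = per_dose.index.to_numpy(dtype=float)
            ys = per_dose.to_numpy(dtype=float)
            order = np.argsort(xs)
            xs, ys = xs[order], ys[order]
            miss = sub[sub[col].isna()]
            doses = miss["dose"].to_numpy(dtype=float)
            inside = (doses >= xs[0]) & (doses <= xs[-1])
            if inside.any():
                filled = np.interp(doses[inside], xs, ys)
                df.loc[miss.index[inside], col] = filled
    return out


def iterative_impute(
    dataset: Dataset,
    max_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 0,
    n_estimators: int = 50,
) -> Dataset:
    """Chained-regression imputation of the numeric input columns.

    Each feature with missing values is modeled as a LightGBM
    regression on all other features (including one-hot indicators of
    the ERM identifier and the categorical inputs, which are fully
    observed), cycling in order of ascending missingness from a
    column-median initialization until ``max_iter`` rounds or the
    largest change of any imputed cell falls below ``tol`` (relative
    to the column scale).
    """
    from lightgbm import LGBMRegressor

    out = dataset.copy()
    df = out.frame
    numeric = [c for c in NUMERIC_INPUTS if c in df.columns]
    fully_missing = [c for c in numeric if df[c].isna().all()]
    if fully_missing:
        raise ValueError(f"columns entirely missing, nothing to learn from: {fully_missing}")
    if not df[numeric].isna().any().any():
        return out

    cat_cols = [c for c in ["erm_id"] + CATEGORICAL_INPUTS if c in df.columns]
    dummies = pd.get_dummies(df[cat_cols].astype(str), dtype=float) if cat_cols else None
    X = df[numeric].astype(float)
    if dummies is not None:
        X = pd.concat([X, dummies], axis=1)

    estimator = LGBMRegressor(
        n_estimators=n_estimators, random_state=seed, verbose=-1, n_jobs=1
    )
    imputer = IterativeImputer(
        estimator=estimator,
        max_iter=max_iter,
        tol=tol,
        initial_strategy="median",
        imputation_order="ascending",
        sample_posterior=False,
        random_state=seed,
    )
    filled = imputer.fit_transform(X.to_numpy(dtype=float))
    df[numeric] = filled[:, : len(numeric)]
    assert not df[numeric].isna().any().any()
    return out


def finalize_features(dataset: Dataset) -> Dataset:
    """Reduce to the final modeling feature set (15 inputs + hazard).

    Drops the organ (encapsulated by the cell line), free-text context
    columns, the near-zero Na 1s / N 1s concentrations, the constant
    24 h duration, the pretreatment flag, and the ERM identifier; the
    viability outcome is discretized into the hazard class.
    """
    df = dataset.frame
    keep = FINAL_NUMERIC + FINAL_CATEGORICAL
    missing = [c for c in keep + ["viability"] if c not in df.columns]
    if missing:
        raise ValueError(f"cannot finalize, columns missing: {missing}")
    out = df[keep].copy()
    out["hazard"] = classify_viability_series(df["viability"])
    roles = {c: "numeric_input" for c in FINAL_NUMERIC}
    roles.update({c: "categorical_input" for c in FINAL_CATEGORICAL})
    roles["hazard"] = "output"
    return Dataset(out, roles)


@dataclass
class OneHotMap:
    """Fitted one-hot encoding: each k-state column becomes k 0/1
    indicator columns named ``column=state`` in sorted state order."""

    state_sets: dict[str, list[str]]

    @classmethod
    def fit(cls, frame: pd.DataFrame, columns: Sequence[str]) -> "OneHotMap":
        states = {c: sorted(frame[c].dropna().astype(str).unique()) for c in columns}
        return cls(states)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col, states in self.state_sets.items():
            vals = out[col].astype(str)
            unseen = sorted(set(vals.unique()) - set(states))
            if unseen:
                raise ValueError(f"unseen state(s) {unseen} in column {col!r}")
            for s in states:
                out[f"{col}={s}"] = (vals == s).astype(float)
            out = out.drop(columns=[col])
        return out

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Recover the original categorical columns by argmax."""
        out = frame.copy()
        for col, states in self.state_sets.items():
            ind = out[[f"{col}={s}" for s in states]].to_numpy(dtype=float)
            out[col] = [states[i] for i in ind.argmax(axis=1)]
            out = out.drop(columns=[f"{col}={s}" for s in states])
        return out


def one_hot(frame: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, OneHotMap]:
    """Fit-and-apply convenience wrapper around :class:`OneHotMap`."""
    enc = OneHotMap.fit(frame, columns)
    return enc.transform(frame), enc


def smote_oversample(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """SMOTE: oversample minority classes to the majority count.

    Each synthetic row is x + u * (x_nn - x) with u ~ Uniform(0, 1)
    and x_nn one of the k same-class Euclidean nearest neighbors of a
    randomly chosen minority row; neighbors are found on z-scored
    features, interpolation happens in the original feature space.
    Original rows are preserved verbatim and come first.
    """
    X = pd.DataFrame(features).reset_index(drop=True)
    y = pd.Series(list(labels), name="label").reset_index(drop=True)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    counts = y.value_counts()
    if (counts < 2).any():
        singletons = counts[counts < 2].index.tolist()
        raise ValueError(f"class(es) with a single member, no neighbor: {singletons}")
    majority = counts.max()
    if (counts == majority).all():
        return X.copy(), y.copy()

    # neighbor geometry on standardized coordinates
    mu = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0).to_numpy()
    rng = np.random.default_rng(seed)
    new_rows, new_labels = [], []
    for cls in counts.index:
        need = majority - counts[cls]
        if need == 0:
            continue
        members = X[y == cls].to_numpy(dtype=float)
        z = (members - mu) / sd
        n_nb = min(k, len(members) - 1)
        nn = NearestNeighbors(n_neighbors=n_nb + 1).fit(z)
        _, nb_idx = nn.kneighbors(z)
        nb_idx = nb_idx[:, 1:]  # drop self
        picks = rng.integers(0, len(members), size=need)
        which_nb = rng.integers(0, n_nb, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        for p, w, uu in zip(picks, which_nb, u):
            parent = members[p]
            neighbor = members[nb_idx[p, w]]
            new_rows.append(parent + uu * (neighbor - parent))
            new_labels.append(cls)
    X_out = pd.concat(
        [X, pd.DataFrame(np.asarray(new_rows), columns=X.columns)], ignore_index=True
    )
    y_out = pd.concat([y, pd.Series(new_labels, name="label")], ignore_index=True)
    return X_out, y_out


@dataclass
class DiscretizationMap:
    """Per-feature ordered tercile edges with low/medium/high labels.

    ``edges[f] = (e1, e2)`` with low = [min, e1), medium = [e1, e2),
    high = [e2, inf); ``data_min``/``data_max`` record the fitted range
    so bins can be reported as numeric ranges.
    """

    edges: dict[str, tuple[float, float]]
    data_min: dict[str, float] = field(default_factory=dict)
    data_max: dict[str, float] = field(default_factory=dict)
    percentiles: tuple[float, float] = (100.0 / 3.0, 200.0 / 3.0)
    labels: tuple[str, ...] = BIN_LABELS

    def assign(self, feature: str, value: float) -> str:
        e1, e2 = self.edges[feature]
        if value < e1:
            return "low"
        if value < e2:
            return "medium"
        return "high"

    def range_text(self, feature: str, label: str) -> str:
        """Human-readable numeric range of one bin, Table-style."""
        e1, e2 = self.edges[feature]
        lo = self.data_min.get(feature, float("nan"))
        if label == "low":
            return f"{lo:g} → {e1:g}"
        if label == "medium":
            return f"{e1:g} → {e2:g}"
        return f">{e2:g}"

    def to_json(self) -> str:
        return json.dumps(
            {
                "percentiles": list(self.percentiles),
                "labels": list(self.labels),
                "features": {
                    f: {
                        "edges": list(self.edges[f]),
                        "min": self.data_min.get(f),
                        "max": self.data_max.get(f),
                    }
                    for f in self.edges
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationMap":
        obj = json.loads(text)
        feats = obj["features"]
        return cls(
            edges={f: tuple(v["edges"]) for f, v in feats.items()},
            data_min={f: v["min"] for f, v in feats.items()},
            data_max={f: v["max"] for f, v in feats.items()},
            percentiles=tuple(obj["percentiles"]),
            labels=tuple(obj["labels"]),
        )


@dataclass
class BinnedDataset:
    """Fully discrete view: every cell is one of a finite state set."""

    frame: pd.DataFrame
    states: dict[str, list[str]]
    outcome: str = "hazard"

    def __post_init__(self):
        if self.frame.isna().any().any():
            raise ValueError("binned dataset must have no missing values")

    def __len__(self) -> int:
        return len(self.frame)


def fit_quantile_bins(
    data: Dataset | pd.DataFrame, columns: Sequence[str] | None = None, q: int = 3
) -> DiscretizationMap:
    """Tercile quantile discretization: edges at the 33.33rd and
    66.67th percentiles (linear-interpolation definition) per column."""
    if q != 3:
        raise ValueError("three equal-sized bins (low/medium/high) are supported")
    df = data.frame if isinstance(data, Dataset) else data
    if columns is None:
        if isinstance(data, Dataset):
            columns = data.columns_with_role("numeric_input")
        else:
            columns = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    edges, mins, maxs = {}, {}, {}
    for col in columns:
        vals = df[col].dropna().to_numpy(dtype=float)
        if len(np.unique(vals)) < q:
            raise ValueError(f"column {col!r} has fewer than {q} distinct values")
        e1, e2 = np.percentile(vals, [100.0 / 3.0, 200.0 / 3.0], method="linear")
        edges[col] = (float(e1), float(e2))
        mins[col] = float(vals.min())
        maxs[col] = float(vals.max())
    return DiscretizationMap(edges=edges, data_min=mins, data_max=maxs)


def apply_bins(data: Dataset | pd.DataFrame, dmap: DiscretizationMap) -> BinnedDataset:
    """Replace numeric inputs by low/medium/high labels (left-closed
    bins, high open-ended; values below the fitted minimum fall in
    low); categorical inputs and the hazard outcome pass through."""
    df = (data.frame if isinstance(data, Dataset) else data).copy()
    states: dict[str, list[str]] = {}
    for col in df.columns:
        if col in dmap.edges:
            e1, e2 = dmap.edges[col]
            vals = df[col].to_numpy(dtype=float)
            lab = np.where(vals < e1, "low", np.where(vals < e2, "medium", "high"))
            df[col] = lab
            states[col] = list(BIN_LABELS)
        else:
            df[col] = df[col].astype(str)
            states[col] = sorted(df[col].unique())
    return BinnedDataset(frame=df, states=states)
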