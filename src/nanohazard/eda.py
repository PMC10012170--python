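"""Exploratory analysis: mixed-type associations, skewness, and a
Mapper-style topological summary of the experiment space.

Numeric-numeric pairs are measured with Spearman's rank correlation,
anything involving a categorical column with Cramér's V (numeric
members tercile-binned first).  Undefined cells (constant columns,
single-state columns) are reported as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .schema import Dataset

__all__ = [
    "spearman_rho",
    "cramers_v",
    "association_matrix",
    "skewness",
    "MapperGraph",
    "mapper_graph",
]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Rows where either member is missing are dropped; a constant vector
    makes the coefficient undefined and returns NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def cramers_v(a: Sequence, b: Sequence) -> float:
    """Cramér's V from the r x c contingency table,
    V = sqrt(chi2 / (n * (min(r, c) - 1))), chi-squared without
    continuity correction and without bias correction.

    0 denotes independence, 1 perfect association; a single-state
    column makes V undefined (NaN).
    """
    a = pd.Series(a)
    b = pd.Series(b)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    keep = a.notna() & b.notna()
    a, b = a[keep].astype(str), b[keep].astype(str)
    table = pd.crosstab(a, b)
    r, c = table.shape
    if min(r, c) < 2:
        return float("nan")
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=False).statistic
    n = table.to_numpy().sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def skewness(x: Sequence[float]) -> float:
    """Adjusted Fisher-Pearson standardized third moment
    (sample-size-corrected); NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        return float("nan")
    return float(stats.skew(x, bias=False))


def _tercile_labels(vals: pd.Series) -> pd.Series:
    """Tercile-bin a numeric vector for numeric-categorical association."""
    arr = vals.to_numpy(dtype=float)
    ok = ~np.isnan(arr)
    e1, e2 = np.percentile(arr[ok], [100.0 / 3.0, 200.0 / 3.0], method="linear")
    lab = np.where(arr < e1, "low", np.where(arr < e2, "medium", "high"))
    out = pd.Series(lab, index=vals.index, dtype=object)
    out[~ok] = np.nan
    return out


def association_matrix(dataset: Dataset, include_output: bool = True) -> pd.DataFrame:
    """Pairwise mixed-type association over all dataset columns.

    The returned square DataFrame carries an ``attrs['method']``
    companion frame tagging each cell 'spearman' or 'cramers_v'.
    """
    df = dataset.frame
    numeric = set(dataset.columns_with_role("numeric_input"))
    cols = [
        c
        for c in df.columns
        if dataset.roles.get(c) in ("numeric_input", "categorical_input")
        or (include_output and dataset.roles.get(c) == "output")
    ]
    if include_output:
        numeric |= {c for c in dataset.columns_with_role("output")
                    if pd.api.types.is_numeric_dtype(df[c])}
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    method = pd.DataFrame("", index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            if ci in numeric and cj in numeric:
                v = spearman_rho(df[ci], df[cj])
                m = "spearman"
            else:
                a = _tercile_labels(df[ci]) if ci in numeric else df[ci]
                b = _tercile_labels(df[cj]) if cj in numeric else df[cj]
                v = cramers_v(a, b)
                m = "cramers_v"
            mat.loc[ci, cj] = mat.loc[cj, ci] = v
            method.loc[ci, cj] = method.loc[cj, ci] = m
    mat.attrs["method"] = method
    return mat


@dataclass
class MapperGraph:
    """Nerve of a covered clustering: nodes are per-interval clusters,
    edges join clusters sharing at least one row."""

    graph: nx.Graph
    n_intervals: int
    overlap: float
    lens_name: str = "lens"

    @property
    def nodes(self):
        return self.graph.nodes(data=True)

    def covered_rows(self) -> set[int]:
        out: set[int] = set()
        for _, data in self.graph.nodes(data=True):
            out.update(data["members"])
        return out

    def to_dot(self) -> str:
        lines = ["graph mapper {"]
        for n, d in self.graph.nodes(data=True):
            lines.append(
                f'  "{n}" [size={d["size"]}, mean_outcome={d["mean_outcome"]:.4g}];'
            )
        for u, v in self.graph.edges:
            lines.append(f'  "{u}" -- "{v}";')
        lines.append("}")
        return "\n".join(lines)


def mapper_graph(
    features: np.ndarray | pd.DataFrame,
    lens: Sequence[float],
    outcome: Sequence[float] | None = None,
    n_intervals: int = 10,
    overlap: float = 0.3,
    linkage_threshold: float = 0.5,
) -> MapperGraph:
    """Mapper topological summary.

    The lens range is covered with ``n_intervals`` intervals with
    fractional ``overlap``; within each preimage, single-linkage
    clustering of the min-max-scaled features is cut at
    ``linkage_threshold``; clusters become nodes (with size and mean
    outcome), and clusters sharing rows are joined by edges.
    """
    X = np.asarray(features, dtype=float)
    lens = np.asarray(lens, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (0.0 < overlap < 1.0):
        raise ValueError("overlap must be in (0, 1)")
    g = nx.Graph()
    if len(X) == 0:
        return MapperGraph(g, n_intervals, overlap)
    out_vals = np.asarray(outcome, dtype=float) if outcome is not None else lens

    # min-max scale features internally
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span

    lmin, lmax = lens.min(), lens.max()
    if lmax == lmin:
        lmax = lmin + 1.0
    width = (lmax - lmin) / (n_intervals - (n_intervals - 1) * overlap)
    step = width * (1.0 - overlap)

    membership: dict[str, np.ndarray] = {}
    for i in range(n_intervals):
        a = lmin + i * step
        b = a + width
        idx = np.flatnonzero((lens >= a - 1e-12) & (lens <= b + 1e-12))
        if len(idx) == 0:
            continue
        if len(idx) == 1:
            labels = np.array([1])
        else:
            z = linkage(pdist(Xs[idx]), method="single")
            labels = fcluster(z, t=linkage_threshold, criterion="distance")
        for lab in np.unique(labels):
            members = idx[labels == lab]
            node = f"i{i}c{lab}"
            membership[node] = members
            g.add_node(
                node,
                members=[int(m) for m in members],
                size=int(len(members)),
                mean_outcome=float(out_vals[members].mean()),
                interval=i,
            )
    names = list(membership)
    for i, u in enumerate(names):
        su = set(membership[u].tolist())
        for v in names[i + 1:]:
            if su & set(membership[v].tolist()):
                g.add_edge(u, v)
    return MapperGraph(g, n_intervals, overlap)
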