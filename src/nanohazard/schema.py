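"""Dataset schema, domain types and closed-form derived quantities.

The experiment table has one row per in-vitro exposure condition of a
silver nanoform (AgNF): system-independent physicochemical descriptors
(XPS atomic concentrations, TEM core size, XRD crystallinity), DLS
system-dependent descriptors measured in cell-culture medium at t0 and
t24, the biological context (organ, cell line, assay, pretreatment),
the exposure dose, and the measured cellular viability in percent.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HazardClass",
    "NanoformProfile",
    "Dataset",
    "COLUMNS",
    "COLUMN_ROLES",
    "NUMERIC_INPUTS",
    "CATEGORICAL_INPUTS",
    "SYSTEM_DEPENDENT",
    "DEFAULT_ALIASES",
    "SchemaError",
    "ParseError",
    "read_dataset",
    "write_dataset",
    "spherical_surface_area",
    "classify_viability",
    "classify_viability_series",
]


class SchemaError(ValueError):
    """A mandatory column is absent or mislabeled."""


class ParseError(ValueError):
    """Non-numeric text found in a numeric column."""


class HazardClass(enum.IntEnum):
    """Cytotoxicity hazard class from cellular viability (ISO 10993-5).

    Ordered from most to least hazardous: very toxic (< 30 % viability),
    toxic (30-70 %), safe (>= 70 %).
    """

    VERY_TOXIC = 0
    TOXIC = 1
    SAFE = 2

    @property
    def label(self) -> str:
        return {0: "very_toxic", 1: "toxic", 2: "safe"}[int(self)]

    @classmethod
    def from_label(cls, label: str) -> "HazardClass":
        mapping = {"very_toxic": cls.VERY_TOXIC, "toxic": cls.TOXIC, "safe": cls.SAFE}
        try:
            return mapping[label]
        except KeyError:
            raise ValueError(f"unknown hazard class label: {label!r}") from None


HAZARD_LABELS = [c.label for c in HazardClass]

COATINGS = ("HEC", "PVP", "CUR", "none")


@dataclass(frozen=True)
class NanoformProfile:
    """System-independent fingerprint of one ERM-identified nanoform.

    Atomic concentrations are XPS surface percentages; core size is the
    TEM number-average diameter in nm; crystallinity and average
    crystallite size come from XRD.
    """

    erm_id: str
    coating: str
    o1s_at: float
    ag3d_at: float
    c1s_at: float
    na1s_at: float
    n1s_at: float
    core_size: float
    crystallinity: float
    avg_crystallite_size: float
    spherical_surface_area: float = field(default=float("nan"))

    def __post_init__(self):
        for name in ("o1s_at", "ag3d_at", "c1s_at", "na1s_at", "n1s_at", "crystallinity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] for {self.erm_id}")
        if self.core_size <= 0:
            raise ValueError(f"core_size must be positive, got {self.core_size}")
        if self.coating not in COATINGS:
            raise ValueError(f"unknown coating {self.coating!r}")
        if math.isnan(self.spherical_surface_area):
            object.__setattr__(
                self, "spherical_surface_area", spherical_surface_area(self.core_size)
            )


# Canonical column order of the experiment table.
COLUMNS = [
    "erm_id",
    "coating",
    "o1s_at",
    "ag3d_at",
    "c1s_at",
    "na1s_at",
    "n1s_at",
    "core_size",
    "spherical_surface_area",
    "crystallinity",
    "avg_crystallite_size",
    "organ",
    "cell_line",
    "cell_type",
    "multiwell",
    "pretreatment",
    "assay",
    "dose",
    "duration",
    "hydro_size_t0",
    "hydro_size_t24",
    "pdi_t0",
    "pdi_t24",
    "viability",
]

NUMERIC_INPUTS = [
    "o1s_at",
    "ag3d_at",
    "c1s_at",
    "na1s_at",
    "n1s_at",
    "core_size",
    "spherical_surface_area",
    "crystallinity",
    "avg_crystallite_size",
    "dose",
    "duration",
    "hydro_size_t0",
    "hydro_size_t24",
    "pdi_t0",
    "pdi_t24",
]

CATEGORICAL_INPUTS = [
    "coating",
    "organ",
    "cell_line",
    "cell_type",
    "multiwell",
    "pretreatment",
    "assay",
]

#: DLS columns measured in medium; targets of dose-wise interpolation.
SYSTEM_DEPENDENT = ["hydro_size_t0", "hydro_size_t24", "pdi_t0", "pdi_t24"]

COLUMN_ROLES: dict[str, str] = {
    **{c: "numeric_input" for c in NUMERIC_INPUTS},
    **{c: "categorical_input" for c in CATEGORICAL_INPUTS},
    "erm_id": "identifier",
    "viability": "output",
}

#: Default aliases mapping spreadsheet-style headers onto canonical names.
DEFAULT_ALIASES: dict[str, str] = {
    "Na 1s_Atomic concentration": "na1s_at",
    "O 1s_Atomic concentration": "o1s_at",
    "Ag 3d_Atomic concentration": "ag3d_at",
    "C 1s_Atomic concentration": "c1s_at",
    "N 1s_Atomic concentration": "n1s_at",
    "core size": "core_size",
    "spherical surface area": "spherical_surface_area",
    "average crystallite sizes": "avg_crystallite_size",
    "av crystallite sizes": "avg_crystallite_size",
    "hydrodynamic size t0": "hydro_size_t0",
    "hydrodynamic size t24": "hydro_size_t24",
    "polydispersity index t0": "pdi_t0",
    "polydispersity index t24": "pdi_t24",
    "pol index t0": "pdi_t0",
    "pol index t24": "pdi_t24",
    "cell line": "cell_line",
    "cell type": "cell_type",
    "exposure dose": "dose",
    "exposure duration": "duration",
    "cellular viability": "viability",
    "ERM": "erm_id",
}


@dataclass
class Dataset:
    """An experiment table plus per-column role tags.

    Thin wrapper over a :class:`pandas.DataFrame` in canonical column
    order; missing cells are NaN (numeric) or NA (categorical).
    """

    frame: pd.DataFrame
    roles: dict[str, str] = field(default_factory=lambda: dict(COLUMN_ROLES))

    def __post_init__(self):
        extra = set(self.frame.columns) - set(self.roles)
        if extra:
            raise SchemaError(f"columns without a role tag: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "Dataset":
        return Dataset(self.frame.copy(), dict(self.roles))

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.frame.columns if self.roles.get(c) == role]

    def schema_json(self) -> str:
        return json.dumps({c: self.roles[c] for c in self.frame.columns}, indent=2)


def spherical_surface_area(core_size: float) -> float:
    """Surface area of a perfect sphere, 4*pi*s**2, with the tabulated
    core-size value plugged directly into the squared term.

    Parameters
    ----------
    core_size : float
        TEM core size in nm; must be non-negative.
    """
    if core_size < 0:
        raise ValueError(f"core_size must be >= 0, got {core_size}")
    return 4.0 * math.pi * core_size**2


def classify_viability(viability: float) -> HazardClass:
    """Map a cellular-viability percentage to its hazard class.

    >= 70 % is safe, [30, 70) is toxic, < 30 % is very toxic
    (ISO 10993-5 thresholds).  Values above 100 % (assay noise) are
    retained and classify as safe.
    """
    if viability is None or (isinstance(viability, float) and math.isnan(viability)):
        raise ValueError("viability must be observed to classify hazard")
    if not math.isfinite(viability):
        raise ValueError(f"viability must be finite, got {viability}")
    if viability >= 70.0:
        return HazardClass.SAFE
    if viability >= 30.0:
        return HazardClass.TOXIC
    return HazardClass.VERY_TOXIC


def classify_viability_series(viability: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_viability` returning label strings."""
    if viability.isna().any():
        raise ValueError("viability must be observed to classify hazard")
    out = pd.Series(
        np.where(
            viability >= 70.0, "safe", np.where(viability >= 30.0, "toxic", "very_toxic")
        ),
        index=viability.index,
    )
    return out


def _canonicalize_columns(df: pd.DataFrame, aliases: Mapping[str, str] | None) -> pd.DataFrame:
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    renamed = {c: table.get(c, c) for c in df.columns}
    return df.rename(columns=renamed)


def read_dataset(
    path: str | Path,
    format: str | None = None,
    sheet: str = "v01",
    aliases: Mapping[str, str] | None = None,
) -> Dataset:
    """Read an experiment table from CSV, TSV or XLSX.

    Header names are mapped through the alias table onto canonical
    names; empty cells become NaN; units are taken as declared (nm, %,
    ppm) with no conversion.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif format == "xlsx":
        xl = pd.ExcelFile(path)
        name = sheet if sheet in xl.sheet_names else xl.sheet_names[0]
        df = xl.parse(name)
    else:
        raise ValueError(f"unknown format {format!r}")

    df = _canonicalize_columns(df, aliases)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory columns missing: {missing}")
    df = df[COLUMNS].copy()
    for col in NUMERIC_INPUTS + ["viability"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at row {row}"
            ) from None
    for col in CATEGORICAL_INPUTS + ["erm_id"]:
        df[col] = df[col].astype("string")
    return Dataset(df.reset_index(drop=True))


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the table as UTF-8 CSV ('.' decimal, empty cell = missing)."""
    dataset.frame.to_csv(path, index=False)


def profiles_from_dataset(dataset: Dataset) -> list[NanoformProfile]:
    """Extract the unique per-ERM system-independent fingerprints."""
    cols = [
        "erm_id", "coating", "o1s_at", "ag3d_at", "c1s_at", "na1s_at", "n1s_at",
        "core_size", "crystallinity", "avg_crystallite_size", "spherical_surface_area",
    ]
    uniq = dataset.frame[cols].drop_duplicates()
    if uniq["erm_id"].duplicated().any():
        dupes = uniq.loc[uniq["erm_id"].duplicated(), "erm_id"].tolist()
        raise ValueError(f"profiles not constant within erm_id: {dupes}")
    return [
        NanoformProfile(
            erm_id=r.erm_id, coating=r.coating, o1s_at=r.o1s_at, ag3d_at=r.ag3d_at,
            c1s_at=r.c1s_at, na1s_at=r.na1s_at, n1s_at=r.n1s_at, core_size=r.core_size,
            crystallinity=r.crystallinity, avg_crystallite_size=r.avg_crystallite_size,
            spherical_surface_area=r.spherical_surface_area,
        )
        for r in uniq.itertuples(index=False)
    ]
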