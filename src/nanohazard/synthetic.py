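"""Synthetic experiment-table generator.

Emulates the statistical structure the downstream analysis assumes:
six ERM-identified nanoforms with fixed system-independent
fingerprints, a log-spaced 0.1-100 ppm dose grid crossed with
cell-line-compatible assays and pretreatments, triplicate viability
measurements following a monotone Hill dose-response, dose-dependent
agglomeration of the hydrodynamic size from t0 to t24, and MCAR
missingness on the DLS columns (47 %) and the spherical surface area
(19 %).

The Hill dose-response and the log-dose agglomeration model are the
minimal mechanisms producing the monotone dose-hazard structure the
Bayesian network must recover; they are config-exposed so tests can
vary them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    COLUMN_ROLES,
    COLUMNS,
    Dataset,
    NanoformProfile,
    SYSTEM_DEPENDENT,
    spherical_surface_area,
)

__all__ = ["GeneratorConfig", "default_profiles", "generate_dataset", "inject_missingness"]


class ConfigError(ValueError):
    pass


def default_profiles() -> list[NanoformProfile]:
    """Six nanoform fingerprints spanning the study's descriptor ranges.

    Core sizes bracket the 7-24 nm TEM range; coatings cover HEC, PVP,
    CUR and uncoated; XPS concentrations are carbon-dominated surfaces
    with trace Na/N, as typical for coated AgNFs.
    """
    rows = [
        # erm_id, coating, o1s, ag3d, c1s, na1s, n1s, core, cryst, crystallite
        ("ERM00000548", "HEC", 34.0, 0.10, 60.6, 0.8, 0.2, 7.0, 61.5, 46.0),
        ("ERM00000549", "PVP", 14.2, 0.19, 61.8, 0.0, 1.6, 15.0, 60.5, 80.0),
        ("ERM00000552", "CUR", 20.5, 8.00, 58.0, 0.3, 0.0, 17.8, 59.0, 98.0),
        ("ERM00000559", "none", 14.5, 15.5, 54.2, 0.0, 0.0, 19.0, 60.0, 105.0),
        ("ERM00000575", "PVP", 25.0, 22.0, 57.0, 1.2, 0.9, 20.0, 45.0, 117.0),
        ("ERM00000580", "HEC", 40.0, 28.0, 65.0, 0.5, 0.4, 24.0, 22.9, 130.0),
    ]
    return [
        NanoformProfile(
            erm_id=e, coating=co, o1s_at=o, ag3d_at=ag, c1s_at=c, na1s_at=na,
            n1s_at=n, core_size=cs, crystallinity=cr, avg_crystallite_size=acs,
        )
        for e, co, o, ag, c, na, n, cs, cr, acs in rows
    ]


#: Median-lethal exposure in ppm per ERM identifier (pristine, MTT).
DEFAULT_EC50 = {
    "ERM00000548": 5.0,
    "ERM00000549": 10.0,
    "ERM00000552": 20.0,
    "ERM00000559": 40.0,
    "ERM00000575": 150.0,
    "ERM00000580": 600.0,
}

#: Multiplicative EC50 shifts for the exposure context.  Digestion-cascade
#: pretreatment mildly increases bioavailable silver (lower EC50); the
#: Alamar-blue readout is mildly protective relative to MTT.
PRETREATMENT_SHIFT = {"none": 1.0, "digested": 0.8, "non-digested": 1.0}
ASSAY_SHIFT = {"MTT": 1.0, "AlamarBlue": 1.1, "WST-1": 1.0}

#: (cell line, assay, pretreatment) arms of the default design.
DEFAULT_ARMS = [
    ("A549", "MTT", "none"),
    ("A549", "AlamarBlue", "none"),
    ("HCT-116", "WST-1", "digested"),
    ("HCT-116", "WST-1", "non-digested"),
    ("HCT-116", "WST-1", "none"),
]


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Defaults reproduce a 900-row table: 6 nanoforms x 5 exposure arms
    x 10 doses x 3 replicates.
    """

    profiles: list[NanoformProfile] = field(default_factory=default_profiles)
    dose_grid: tuple[float, ...] = (0.1, 1.0, 1.25, 2.5, 5.0, 10.0, 20.0, 25.0, 50.0, 100.0)
    replicates: int = 3
    arms: list[tuple[str, str, str]] = field(default_factory=lambda: list(DEFAULT_ARMS))
    ec50: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EC50))
    hill_slope: float = 1.8
    noise_sd: float = 4.0
    agglomeration_rate: float = 0.25
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "hydro_size_t0": 0.47,
            "hydro_size_t24": 0.47,
            "pdi_t0": 0.47,
            "pdi_t24": 0.47,
            "spherical_surface_area": 0.19,
        }
    )
    anchor_doses: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.profiles:
            raise ConfigError("profile list is empty")
        if not self.dose_grid:
            raise ConfigError("dose grid is empty")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.hill_slope <= 0:
            raise ConfigError("hill_slope must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for p in self.profiles:
            if self.ec50.get(p.erm_id, 1.0) <= 0:
                raise ConfigError(f"ec50 must be > 0 for {p.erm_id}")
        for col, r in self.missing_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"missing rate for {col} outside [0,1]")
            if col in ("viability", "erm_id", "dose"):
                raise ConfigError(f"missingness may not target {col}")


def _arm_ec50(cfg: GeneratorConfig, erm_id: str, cell_line: str, assay: str,
              pretreatment: str) -> float:
    return cfg.ec50[erm_id] * PRETREATMENT_SHIFT[pretreatment] * ASSAY_SHIFT[assay]


def generate_dataset(config: GeneratorConfig | None = None) -> Dataset:
    """Generate a complete experiment table, then apply MCAR missingness.

    Viability follows V = 100 / (1 + (dose/EC50)^h) + eps with
    eps ~ Normal(0, noise_sd) per replicate.  The DLS state is one
    measurement per exposure condition (shared by replicates):
    hydro_size_t24 = hydro_size_t0 * (1 + rate * log10(1 + dose)),
    with the polydispersity index growing with the same agglomeration
    term.  Deterministic given config.seed.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    rows = []
    for profile in cfg.profiles:
        for cell_line, assay, pretreatment in cfg.arms:
            ec50 = _arm_ec50(cfg, profile.erm_id, cell_line, assay, pretreatment)
            # one DLS baseline per (nanoform, arm): size scales with the
            # core and the medium; HCT medium agglomerates slightly more
            t0 = 55.0 + 8.0 * profile.core_size + (25.0 if cell_line == "HCT-116" else 0.0)
            pdi0 = min(0.18 + 0.02 * profile.core_size, 0.75)
            for dose in cfg.dose_grid:
                growth = cfg.agglomeration_rate * np.log10(1.0 + dose)
                t24 = t0 * (1.0 + growth)
                pdi24 = min(pdi0 * (1.0 + 0.8 * growth), 1.5)
                mean_v = 100.0 / (1.0 + (dose / ec50) ** cfg.hill_slope)
                eps = rng.normal(0.0, cfg.noise_sd, cfg.replicates) if cfg.noise_sd > 0 \
                    else np.zeros(cfg.replicates)
                for k in range(cfg.replicates):
                    rows.append({
                        "erm_id": profile.erm_id,
                        "coating": profile.coating,
                        "o1s_at": profile.o1s_at,
                        "ag3d_at": profile.ag3d_at,
                        "c1s_at": profile.c1s_at,
                        "na1s_at": profile.na1s_at,
                        "n1s_at": profile.n1s_at,
                        "core_size": profile.core_size,
                        "spherical_surface_area": profile.spherical_surface_area,
                        "crystallinity": profile.crystallinity,
                        "avg_crystallite_size": profile.avg_crystallite_size,
                        "organ": "lung" if cell_line == "A549" else "intestine",
                        "cell_line": cell_line,
                        "cell_type": "epithelial",
                        "multiwell": "96-well",
                        "pretreatment": pretreatment,
                        "assay": assay,
                        "dose": dose,
                        "duration": 24.0,
                        "hydro_size_t0": t0,
                        "hydro_size_t24": t24,
                        "pdi_t0": pdi0,
                        "pdi_t24": pdi24,
                        "viability": max(mean_v + eps[k], 0.0),
                    })
    frame = pd.DataFrame(rows, columns=COLUMNS)
    for col in ("erm_id",) + tuple(c for c in frame.columns if frame[c].dtype == object):
        frame[col] = frame[col].astype("string")
    dataset = Dataset(frame)

    if cfg.anchor_doses is not None:
        mask = ~frame["dose"].isin(list(cfg.anchor_doses))
        for col in SYSTEM_DEPENDENT:
            dataset.frame.loc[mask, col] = np.nan
    if cfg.missing_rates:
        dataset = inject_missingness(dataset, cfg.missing_rates, seed=cfg.seed + 1)
    return dataset


def inject_missingness(
    dataset: Dataset, missing_rates: Mapping[str, float], seed: int
) -> Dataset:
    """Blank each targeted cell independently with its column rate (MCAR).

    Outcome and identifier columns are never blanked; deterministic
    given seed.
    """
    out = dataset.copy()
    rng = np.random.default_rng(seed)
    for col, rate in missing_rates.items():
        role = out.roles.get(col)
        if role in ("output", "identifier"):
            raise ConfigError(f"missingness may not target {role} column {col!r}")
        if col not in out.frame.columns:
            raise ConfigError(f"unknown column {col!r}")
        if not (0.0 <= rate <= 1.0):
            raise ConfigError(f"rate for {col!r} outside [0,1]")
        if rate == 0.0:
            continue
        mask = rng.random(len(out.frame)) < rate
        out.frame.loc[mask, col] = np.nan
    return out
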