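"""Readers/writers, packaged reference tables, and pipeline configuration.

The packaged reference data are the published results for the studied
series of 27 fused benzimidazole derivatives:

* ``iop_activity_27.csv`` — per-compound hypotensive predictors (ED20
  mg/kg, Index, ED20 umol/kg, Level) and the binary IOP activity class;
* ``pharmacophore_presence.csv`` / ``pharmacophore_absence.csv`` — the
  published descriptor tables (structure tokens, length, bond code, class
  frequencies Pa/Pi and hypergeometric significance Pr) for descriptors
  flagged as pharmacophores of presence/absence of IOP-lowering activity.

The published descriptor tables print columns run together; the packaged
CSVs are this package's canonical transcription (the 0/1 digit following a
bond-path code is kept as part of the BD token, and unicode minus/ellipsis
are ASCII ``-``/``...``).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import ActivityProfile, index_from_ed20
from .chem import DescriptorProfile, DescriptorKey

ACTIVITY_COLUMNS = ["code", "ed20_mg_kg", "index", "ed20_umol_kg", "level",
                    "iop_cluster"]


def _data_path(name: str):
    return resources.files("iopqsar.data").joinpath(name)


# ---------------------------------------------------------------------------
# Activity tables
# ---------------------------------------------------------------------------

def load_activity_table(path, on_inconsistent: str = "error") -> list[ActivityProfile]:
    """Read an activity CSV into typed profiles.

    Checks the Index-consistency invariant (Index must equal the potency
    scale applied to ED20); violations raise or warn per
    ``on_inconsistent`` ("error" | "warn").
    """
    df = pd.read_csv(path)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns and c != "iop_cluster"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty activity table")
    out = []
    for _, row in df.iterrows():
        code = str(row["code"])
        ed20 = float(row["ed20_mg_kg"])
        if not ed20 > 0:
            raise ValueError(f"{path}: row {code!r} has non-positive ED20 {ed20}")
        prof = ActivityProfile(
            code=code,
            ed20_mg_kg=ed20,
            index_points=int(row["index"]),
            ed20_umol_kg=float(row["ed20_umol_kg"]),
            level=int(row["level"]),
            iop_cluster=None if "iop_cluster" not in df.columns
            else int(row["iop_cluster"]),
        )
        expect = index_from_ed20(prof.ed20_mg_kg)
        if prof.index_points != expect:
            msg = (f"{path}: row {code!r} Index {prof.index_points} inconsistent "
                   f"with ED20 {prof.ed20_mg_kg} mg/kg (expected {expect})")
            if on_inconsistent == "error":
                raise ValueError(msg)
            warnings.warn(msg)
        out.append(prof)
    return out


def save_activity_table(profiles, path) -> None:
    pd.DataFrame(
        [
            {
                "code": p.code,
                "ed20_mg_kg": p.ed20_mg_kg,
                "index": p.index_points,
                "ed20_umol_kg": p.ed20_umol_kg,
                "level": p.level,
                "iop_cluster": p.iop_cluster,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)


def load_reference_activity() -> list[ActivityProfile]:
    """The packaged 27-compound activity table for the studied series."""
    with resources.as_file(_data_path("iop_activity_27.csv")) as p:
        return load_activity_table(p)


# ---------------------------------------------------------------------------
# Pharmacophore tables
# ---------------------------------------------------------------------------

def load_pharmacophore_table(path) -> pd.DataFrame:
    """Read a pharmacophore CSV (sd1, ld, sd2, bd, pa, pi, pr)."""
    df = pd.read_csv(
        path,
        dtype={"sd1": "string", "sd2": "string", "bd": "string"},
        keep_default_na=False,
        na_values=[""],
    )
    for col in ("pa", "pi", "pr"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        df[col] = df[col].astype(float)
    return df


def load_reference_pharmacophores(kind: str) -> pd.DataFrame:
    """The packaged published pharmacophore table, ``kind`` in
    {"presence", "absence"}."""
    if kind not in ("presence", "absence"):
        raise ValueError(f"kind must be 'presence' or 'absence', got {kind!r}")
    with resources.as_file(_data_path(f"pharmacophore_{kind}.csv")) as p:
        return load_pharmacophore_table(p)


def check_pharmacophore_table(df: pd.DataFrame, kind: str,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Re-apply the decision rule to a printed table; return violating rows."""
    if kind == "presence":
        ok = (df["pa"] > df["pi"]) & (df["pr"] <= alpha)
    elif kind == "absence":
        ok = (df["pi"] > df["pa"]) & (df["pr"] <= alpha)
    else:
        raise ValueError(f"kind must be 'presence' or 'absence', got {kind!r}")
    return df.loc[~ok]


# ---------------------------------------------------------------------------
# Descriptor profiles and enrichment tables
# ---------------------------------------------------------------------------

def save_profiles(profiles, path) -> None:
    """Long-format CSV: molecule_id, sd1, ld, sd2, bd, count."""
    rows = []
    for prof in profiles:
        for key, count in sorted(prof.counts.items(),
                                 key=lambda kv: kv[0].sort_key):
            sd1, ld, sd2, bd = key.as_tuple()
            rows.append(
                {"molecule_id": prof.molecule_id, "sd1": sd1, "ld": ld,
                 "sd2": sd2, "bd": bd, "count": count}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_profiles(path) -> list[DescriptorProfile]:
    df = pd.read_csv(path, dtype={"sd1": "string", "sd2": "string",
                                  "bd": "string"},
                     keep_default_na=False, na_values=[""])
    out = []
    for mol_id, group in df.groupby("molecule_id", sort=False):
        prof = DescriptorProfile(molecule_id=str(mol_id))
        for _, row in group.iterrows():
            key = DescriptorKey.canonical(
                sd1=None if pd.isna(row["sd1"]) else str(row["sd1"]),
                ld=None if row["ld"] in ("", None) or pd.isna(row["ld"])
                else int(row["ld"]),
                sd2=None if pd.isna(row["sd2"]) else str(row["sd2"]),
                bd=None if pd.isna(row["bd"]) else str(row["bd"]),
            )
            prof.counts[key] += int(row["count"])
        out.append(prof)
    return out


def save_enrichment(df: pd.DataFrame, path) -> None:
    """Enrichment CSV mirroring the published layout; Pr in scientific
    notation (e.g. 3.79E-02)."""
    out = df.copy()
    out["pr"] = out["pr"].map(lambda p: f"{p:.2E}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; round-trips through JSON."""

    seed: int = 0
    max_length: int = 5
    frequency_mode: str = "occurrence"
    alpha: float = 0.05
    kmeans_restarts: int = 50
    n_networks: int = 1000
    n_retain: int = 50
    hidden_min: int = 3
    hidden_max: int = 10
    train_fraction: float = 0.8
    max_epochs: int = 500
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))
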