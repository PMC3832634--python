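"""Tabular I/O, configuration and validation for the pipeline.

Column contracts
----------------
Species-means CSV (one row per species, natural units):
    species (required), body_mass (required, grams, > 0), plus any trait
    columns such as forelimb_length, hindlimb_moi, ...; optional group
    columns ``order`` and ``specialization``.

Pendulum-trials CSV (one row per measured limb, SI units):
    limb_id, species, limb_type (fore|hind), limb_mass (kg), bar_mass (kg),
    bar_com (m), bar_moi (kg m^2), reading_near, reading_far (N),
    support_separation (m), near_support_offset (m), period (s), length (m).

Body mass arrives in grams (the convention of the source tables) and all
slopes are invariant to that choice; pendulum records are SI throughout.
Every dropped or modified row is logged with a reason — no silent
coercion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .inertial import BarSpec, InertialProperties, PendulumTrial

__all__ = [
    "SchemaError",
    "AnalysisConfig",
    "read_species_csv",
    "read_trials_csv",
    "write_inertial_csv",
    "load_groups_yaml",
    "default_groups",
]

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = [
    f"{limb}limb_{t}"
    for limb in ("fore", "hind")
    for t in ("length", "mass", "com", "moi", "radius", "freq")
]

TRIAL_COLUMNS = [
    "limb_id", "species", "limb_type", "limb_mass", "bar_mass", "bar_com",
    "bar_moi", "reading_near", "reading_far", "support_separation",
    "near_support_offset", "period", "length",
]


class SchemaError(ValueError):
    """A file does not meet its documented column contract."""


def read_species_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a species-means table.

    Rejects missing mandatory columns, duplicate species and non-positive
    body masses (row-level rejection, logged).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty file")
    missing = [c for c in ("species", "body_mass") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicated species {sorted(set(dupes))}")
    bad = df["body_mass"] <= 0
    if bad.any():
        for sp in df.loc[bad, "species"]:
            logger.warning("%s: rejected row %s (non-positive body mass)", path, sp)
        df = df[~bad].copy()
    if len(df) < 3:
        raise SchemaError(f"{path}: fewer than 3 usable rows")
    return df.reset_index(drop=True)


def read_trials_csv(path: str | Path) -> List[dict]:
    """Read pendulum-trial records into typed rows.

    Returns a list of dicts with keys ``limb_id``, ``species``,
    ``limb_type``, ``trial`` (:class:`PendulumTrial`) and ``length``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    rows = []
    for _, rec in df.iterrows():
        if rec["limb_type"] not in ("fore", "hind"):
            raise SchemaError(
                f"{path}: limb_type must be 'fore' or 'hind', got {rec['limb_type']!r}"
            )
        bar = BarSpec(
            mass=float(rec["bar_mass"]),
            com_distance_from_pivot=float(rec["bar_com"]),
            moi_about_pivot=float(rec["bar_moi"]),
        )
        trial = PendulumTrial(
            limb_mass=float(rec["limb_mass"]),
            bar=bar,
            scale_reading_near=float(rec["reading_near"]),
            scale_reading_far=float(rec["reading_far"]),
            support_separation=float(rec["support_separation"]),
            near_support_offset_from_pivot=float(rec["near_support_offset"]),
            oscillation_period=float(rec["period"]),
        )
        rows.append({
            "limb_id": rec["limb_id"],
            "species": rec["species"],
            "limb_type": rec["limb_type"],
            "trial": trial,
            "length": float(rec["length"]),
        })
    return rows


def write_inertial_csv(
    records: Sequence[Tuple[str, str, str, InertialProperties]], path: str | Path
) -> None:
    """Write (limb_id, species, limb_type, properties) rows to CSV."""
    out = pd.DataFrame([
        {
            "limb_id": lid, "species": sp, "limb_type": lt,
            "length": p.length, "mass": p.mass, "com_position": p.com_position,
            "moi": p.moi, "radius_of_gyration": p.radius_of_gyration,
            "natural_frequency": p.natural_frequency,
            "warnings": "; ".join(p.warnings),
        }
        for lid, sp, lt, p in records
    ])
    out.to_csv(path, index=False)


def load_groups_yaml(path: str | Path) -> Dict[str, List[str]]:
    """Group definitions: mapping of group name -> list of species."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not all(
        isinstance(v, list) for v in raw.values()
    ):
        raise SchemaError(f"{path}: expected a mapping of group -> species list")
    return {str(k): [str(s) for s in v] for k, v in raw.items()}


def default_groups(df: pd.DataFrame, min_n: int = 8) -> Dict[str, List[str]]:
    """Analysis groups from the metadata columns.

    Taxonomic orders with at least ``min_n`` species, plus the cursorial
    locomotor group when a ``specialization`` column is present.
    """
    groups: Dict[str, List[str]] = {}
    if "order" in df.columns:
        for name, sub in df.groupby("order"):
            if len(sub) >= min_n:
                groups[str(name)] = sub["species"].tolist()
    if "specialization" in df.columns:
        cursors = df[df["specialization"].astype(str).str.contains(
            "cursorial", case=False, na=False)]
        if len(cursors) >= min_n:
            groups["Cursors"] = cursors["species"].tolist()
    return groups


@dataclass
class AnalysisConfig:
    """Resolved configuration for an end-to-end `report` run."""

    data: str
    out_dir: str
    tree: Optional[str] = None
    traits: List[str] = field(default_factory=lambda: list(TRAIT_COLUMNS))
    groups_file: Optional[str] = None
    branch_mode: str = "divergence_times"
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "data" not in raw or "out_dir" not in raw:
            raise SchemaError(f"{path}: 'data' and 'out_dir' are required")
        cfg = cls(**raw)
        if cfg.branch_mode not in ("divergence_times", "unity", "both"):
            raise SchemaError(
                "branch_mode must be 'divergence_times', 'unity' or 'both'"
            )
        return cfg

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)
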