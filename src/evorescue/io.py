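"""Reading and writing trait tables, trajectories and parameter files."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .gradual import GradualSiteParams, SnowmeltModel, aggregata_params, hybrid_params
from .selection import TRAIT_COLUMN
from .step import StepParams
from .trajectory import Trajectory

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trait_table",
    "write_trait_table",
    "write_trajectory",
    "read_trajectory",
    "load_config",
    "write_run_summary",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("plant_id", "site", "year", TRAIT_COLUMN, "survival")

PathLike = Union[str, Path]


def read_trait_table(path: PathLike, drop_missing: bool = True) -> pd.DataFrame:
    """Read and validate a plant-level trait/fitness CSV.

    Required header: plant_id, site, year, sla_cm2_per_g, survival.
    Survival must be binary {0, 1}; traits must be positive; (plant_id,
    year) pairs must be unique.  Violations raise a ``ValueError`` naming
    the offending row (1-based, excluding the header) and column.  Records
    with missing trait or survival are dropped with a logged count when
    ``drop_missing``.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    n0 = len(table)
    if drop_missing:
        table = table.dropna(subset=[TRAIT_COLUMN, "survival"])
        dropped = n0 - len(table)
        if dropped:
            logger.info("%s: dropped %d rows with missing trait/survival", path, dropped)

    surv = pd.to_numeric(table["survival"], errors="coerce")
    bad = table.index[~surv.isin([0, 1])]
    if len(bad):
        row = int(bad[0]) + 1
        raise ValueError(
            f"{path}: non-binary value in column 'survival' at data row {row}"
        )
    table["survival"] = surv.astype(int)

    trait = pd.to_numeric(table[TRAIT_COLUMN], errors="coerce")
    bad = table.index[~np.isfinite(trait) | (trait <= 0)]
    if len(bad):
        row = int(bad[0]) + 1
        raise ValueError(
            f"{path}: non-positive or unparseable value in column "
            f"'{TRAIT_COLUMN}' at data row {row}"
        )
    table[TRAIT_COLUMN] = trait.astype(float)

    dup = table.duplicated(subset=["plant_id", "year"])
    if dup.any():
        row = int(table.index[dup][0]) + 1
        raise ValueError(f"{path}: duplicate (plant_id, year) at data row {row}")
    logger.info("%s: read %d records", path, len(table))
    return table.reset_index(drop=True)


def write_trait_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


TRAJECTORY_COLUMNS_STEP = ["generation", "delta_z", "plastic_shift", "w_mean", "n"]
TRAJECTORY_COLUMNS_GRADUAL = [
    "year",
    "generation",
    "snowmelt_day",
    "delta_z",
    "plastic_shift",
    "displacement",
    "w_mean",
    "n",
    "is_generation",
]


def write_trajectory(path: PathLike, traj: Trajectory) -> None:
    """Write a trajectory as CSV with a fixed column order, full precision."""
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    cols = (
        TRAJECTORY_COLUMNS_GRADUAL
        if "year" in traj.data.columns
        else TRAJECTORY_COLUMNS_STEP
    )
    traj.data.to_csv(path, index=False, columns=cols, float_format="%.17g")


def read_trajectory(path: PathLike, extinction_threshold: float = 2.0) -> Trajectory:
    data = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(data, extinction_threshold)


_STEP_KEYS = {f.name for f in StepParams.__dataclass_fields__.values()}
_GRADUAL_KEYS = {f.name for f in GradualSiteParams.__dataclass_fields__.values()}
_SNOW_KEYS = {f.name for f in SnowmeltModel.__dataclass_fields__.values()}


def load_config(path: PathLike) -> dict:
    """Load a YAML parameter file into model parameter objects.

    Recognized top-level sections: ``step`` (StepParams fields), ``gradual``
    (GradualSiteParams fields, or ``site: hybrid``/``aggregata`` plus
    overrides) and ``snowmelt`` (SnowmeltModel fields).  Unknown sections or
    keys are rejected so typos cannot silently fall back to defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"step", "gradual", "snowmelt"}
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
    out: dict = {}
    if "step" in raw:
        bad = set(raw["step"]) - _STEP_KEYS
        if bad:
            raise ValueError(f"{path}: unknown step keys {sorted(bad)}")
        out["step"] = StepParams(**raw["step"])
    if "gradual" in raw:
        section = dict(raw["gradual"])
        bad = set(section) - _GRADUAL_KEYS
        if bad:
            raise ValueError(f"{path}: unknown gradual keys {sorted(bad)}")
        site = section.pop("site", None)
        if site == "hybrid":
            out["gradual"] = hybrid_params(**section)
        elif site == "aggregata":
            out["gradual"] = aggregata_params(**section)
        else:
            out["gradual"] = GradualSiteParams(site=site or "custom", **section)
    if "snowmelt" in raw:
        bad = set(raw["snowmelt"]) - _SNOW_KEYS
        if bad:
            raise ValueError(f"{path}: unknown snowmelt keys {sorted(bad)}")
        out["snowmelt"] = SnowmeltModel(**raw["snowmelt"])
    return out


def write_run_summary(path: PathLike, summary: dict) -> None:
    """Write a JSON run summary (resolved parameters, seed, headline results)."""

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=default)
        fh.write("\n")
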