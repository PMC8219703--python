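"""File formats and configuration.

Canonical interchange format is a long (tidy) concentration CSV, one row per
measurement::

    compound,matrix,sampler,flume,day,concentration,below_loq
    acesulfame,SW,,1,0,11.5,False
    acesulfame,PW,A,1,1,7.91,False

Units in files are days and ug/L (declared in a leading comment line);
conversion to the internal hours happens at this boundary only.  Porewater
(PW) rows must name a sampler A--D; surface-water (SW) rows leave it blank.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .inference import LOQ_SUBSTITUTION_FACTOR, ObservationSet
from .synthetic import HOURS_PER_DAY, SyntheticDataset
from .transport import BoundarySeries

__all__ = [
    "ValidationError",
    "SCHEMA_COLUMNS",
    "read_concentrations",
    "write_concentrations",
    "dataset_to_records",
    "records_to_inputs",
    "default_config",
    "load_config",
]

SCHEMA_COLUMNS = ["compound", "matrix", "sampler", "flume", "day",
                  "concentration", "below_loq"]
_UNITS_HEADER = "# units: day=d concentration=ug/L"
SAMPLERS = ("A", "B", "C", "D")


class ValidationError(ValueError):
    """Malformed concentration records; the message lists offending rows."""


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    df = df[SCHEMA_COLUMNS].copy()
    df["sampler"] = df["sampler"].fillna("").astype(str)
    df["matrix"] = df["matrix"].astype(str)
    df["below_loq"] = df["below_loq"].astype(bool)
    problems = []
    bad_matrix = ~df["matrix"].isin(["SW", "PW"])
    for idx in df.index[bad_matrix]:
        problems.append(f"row {idx}: matrix must be SW or PW, got {df.at[idx, 'matrix']!r}")
    pw_bad = (df["matrix"] == "PW") & ~df["sampler"].isin(SAMPLERS)
    for idx in df.index[pw_bad]:
        problems.append(f"row {idx}: PW record needs a sampler in {SAMPLERS}, "
                        f"got {df.at[idx, 'sampler']!r}")
    sw_bad = (df["matrix"] == "SW") & (df["sampler"] != "")
    for idx in df.index[sw_bad]:
        problems.append(f"row {idx}: SW record must leave the sampler blank")
    for col, cond in [("day", df["day"] < 0), ("concentration", df["concentration"] < 0)]:
        for idx in df.index[cond | df[col].isna()]:
            problems.append(f"row {idx}: {col} must be a number >= 0")
    key = ["compound", "matrix", "sampler", "flume", "day"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        for keyval, grp in df[dup].groupby(key):
            rows = ", ".join(str(i) for i in grp.index)
            problems.append(f"duplicate key {tuple(keyval)} in rows {rows}")
    if problems:
        raise ValidationError("invalid concentration records:\n  "
                              + "\n  ".join(problems))
    return df


def read_concentrations(path) -> pd.DataFrame:
    """Read and validate a tidy concentration CSV (days, ug/L)."""
    df = pd.read_csv(path, comment="#",
                     dtype={"compound": str, "matrix": str, "sampler": str,
                            "flume": int, "day": float,
                            "concentration": float, "below_loq": bool})
    return _validate(df)


def write_concentrations(records: pd.DataFrame, path) -> None:
    """Write validated records with the units header; round-trips losslessly."""
    df = _validate(pd.DataFrame(records))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER + "\n")
        df.to_csv(fh, index=False)


def dataset_to_records(dataset: SyntheticDataset, flume: int = 1) -> pd.DataFrame:
    """Flatten a synthetic dataset into the tidy CSV schema."""
    rows = []
    for compound, boundary in sorted(dataset.boundaries.items()):
        for t, c in zip(boundary.times, boundary.concentrations):
            rows.append({"compound": compound, "matrix": "SW", "sampler": "",
                         "flume": flume, "day": t / HOURS_PER_DAY,
                         "concentration": c, "below_loq": False})
    for obs in dataset.observations:
        for t, c, flag in zip(obs.times, obs.concentrations, obs.censored):
            rows.append({"compound": obs.compound, "matrix": "PW",
                         "sampler": obs.flowpath.upper(), "flume": flume,
                         "day": t / HOURS_PER_DAY, "concentration": c,
                         "below_loq": bool(flag)})
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)


def records_to_inputs(
    df: pd.DataFrame, loq: Mapping[str, float] | float = 0.1
) -> tuple[dict[str, BoundarySeries], list[ObservationSet]]:
    """Convert tidy records into boundary series and observation sets (hours).

    ``loq`` is a per-compound mapping or a single value; rows flagged
    ``below_loq`` are (re)substituted with LOQ / sqrt(2) so downstream
    invariants hold regardless of how the file rounded them.
    """
    df = _validate(df)

    def loq_of(compound: str) -> float:
        if isinstance(loq, Mapping):
            return float(loq.get(compound, loq.get("default", 0.1)))
        return float(loq)

    boundaries: dict[str, BoundarySeries] = {}
    observations: list[ObservationSet] = []
    for compound, grp in df[df["matrix"] == "SW"].groupby("compound"):
        grp = grp.sort_values("day")
        boundaries[compound] = BoundarySeries(
            grp["day"].to_numpy() * HOURS_PER_DAY,
            grp["concentration"].to_numpy(),
        )
    pw = df[df["matrix"] == "PW"]
    for (compound, sampler), grp in pw.groupby(["compound", "sampler"]):
        grp = grp.sort_values("day")
        values = grp["concentration"].to_numpy(dtype=float).copy()
        flags = grp["below_loq"].to_numpy(dtype=bool)
        lq = loq_of(compound)
        values[flags] = lq * LOQ_SUBSTITUTION_FACTOR
        observations.append(ObservationSet(
            compound=compound, flowpath=sampler.lower(),
            times=grp["day"].to_numpy() * HOURS_PER_DAY,
            concentrations=values, loq=lq, censored=flags,
        ))
    return boundaries, observations


def default_config() -> dict:
    """Schema defaults reproducing the study setup; see docs/methods.md."""
    return {
        "reference_compound": "hydrochlorothiazide",
        "flowpaths": {
            "a": {"length_m": 0.05, "travel_time_h": 11.5},
            "b": {"length_m": 0.111, "travel_time_h": 24.3},
            "c": {"length_m": 0.166, "travel_time_h": 43.3},
            "d": {"length_m": 0.092, "travel_time_h": 20.1},
        },
        "priors": {
            "relative_sd": 0.2,
            "k_bounds": [1e-5, 4.0],
            "R_bounds": [1.0, 49.0],
            "stage1_D_bounds": [1e-6, 1e-2],
        },
        "solver": {"domain_m": 0.25, "n_cells": 40, "dt_h": 1.0,
                   "duration_h": 504.0},
        "dream": {"chains": 20, "generations": 4004, "burn_in": 0.5},
        "likelihood": {"sigma_mode": "jeffreys", "sigma": None},
        "reporting": {"rel_sd": 0.05},
        "loq": {"default": 0.1},
    }


def load_config(path=None) -> dict:
    """Load a YAML config, merged (one level deep) over the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg
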