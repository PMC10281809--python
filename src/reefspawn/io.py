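"""Delimited-table readers/writers and run configuration.

Fish table schema (CSV/TSV, header required, ISO-8601 dates, lengths mm):
fish_id, collection_date, total_length_mm, fork_length_mm, weight_g,
count1, count2, count3, pre_settlement_count — blanks allowed in the
optional columns. Environment table: date, sst_C, rainfall_mm,
flood_height_m.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .ageing import FISH_COLUMNS, MAX_TOTAL_LENGTH_MM

__all__ = ["RunConfig", "read_fish_table", "read_env_table", "write_table"]

_MANDATORY = ["fish_id", "collection_date", "total_length_mm"]
_ENV_MANDATORY = ["date", "sst_C", "rainfall_mm"]


def read_fish_table(path: str | Path, sep: str = ",") -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a fish table.

    Rows violating invariants (total length > 250 mm, unparseable dates,
    non-positive lengths) are rejected; the second return value lists
    row-numbered rejection messages. Missing mandatory columns or
    duplicated fish ids raise.
    """
    df = pd.read_csv(path, sep=sep)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"fish table missing mandatory column {col!r}")
    if df["fish_id"].duplicated().any():
        dups = df.loc[df["fish_id"].duplicated(), "fish_id"].unique()[:5]
        raise ValueError(f"duplicated fish_id values: {list(dups)}")
    for col in FISH_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    rejected: list[str] = []
    keep = []
    dates = pd.to_datetime(df["collection_date"], errors="coerce")
    for i, row in df.iterrows():
        if pd.isna(dates.iloc[i]):
            rejected.append(f"row {i + 2}: unparseable collection_date {row['collection_date']!r}")
        elif pd.isna(row["total_length_mm"]) or row["total_length_mm"] <= 0:
            rejected.append(f"row {i + 2}: non-positive total_length_mm")
        elif row["total_length_mm"] > MAX_TOTAL_LENGTH_MM:
            rejected.append(f"row {i + 2}: total_length_mm {row['total_length_mm']} exceeds {MAX_TOTAL_LENGTH_MM}")
        else:
            keep.append(i)
    out = df.loc[keep].copy()
    out["collection_date"] = pd.to_datetime(out["collection_date"]).dt.date
    return out.reset_index(drop=True), rejected


def read_env_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    for col in _ENV_MANDATORY:
        if col not in df.columns:
            raise ValueError(f"environment table missing mandatory column {col!r}")
    if "flood_height_m" not in df.columns:
        df["flood_height_m"] = 0.0
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved pipeline configuration; every run emits it alongside outputs."""

    seed: int = 1
    fish_table: str | None = None
    env_table: str | None = None
    output_dir: str = "reefspawn_out"
    qc_count_tolerance: float = 0.10
    pld_mean_override: float | None = None
    cohort_gap_days: int = 30
    min_fish_per_year: int = 30
    gam_k_grid: tuple = (8, 12, 16, 20)
    gam_p_min: float = 1.05
    gam_p_max: float = 1.95
    gam_n_p: int = 10
    peak_ci_draws: int = 200
    closure_durations: tuple = (5, 9)
    closure_counts: tuple = (1, 2, 3)
    closure_anchor_offset_days: int = 0
    synthetic: dict = field(default_factory=dict)  # non-empty => simulate inputs

    def __post_init__(self) -> None:
        if self.qc_count_tolerance <= 0:
            raise ValueError("qc tolerance must be positive")
        if self.cohort_gap_days <= 0:
            raise ValueError("cohort gap must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        nested = {
            "paths": {"fish_table": "fish_table", "env_table": "env_table", "output_dir": "output_dir"},
            "qc": {"count_tolerance": "qc_count_tolerance"},
            "pld": {"mean_override": "pld_mean_override"},
            "cohorts": {"gap_days": "cohort_gap_days"},
            "gam": {"k_grid": "gam_k_grid", "p_min": "gam_p_min", "p_max": "gam_p_max",
                    "n_p": "gam_n_p", "ci_draws": "peak_ci_draws"},
            "closures": {"durations": "closure_durations", "counts": "closure_counts",
                         "anchor_offset_days": "closure_anchor_offset_days"},
        }
        for key, val in raw.items():
            if key in nested and isinstance(val, dict):
                for k2, attr in nested[key].items():
                    if k2 in val:
                        flat[attr] = val[k2]
            elif key in {f.name for f in dataclasses.fields(cls)}:
                flat[key] = val
            else:
                raise ValueError(f"unknown config key {key!r}")
        for tup_key in ("gam_k_grid", "closure_durations", "closure_counts"):
            if tup_key in flat:
                flat[tup_key] = tuple(flat[tup_key])
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
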