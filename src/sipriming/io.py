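"""Delimited-text readers and writers for the pipeline's tables.

All tables are UTF-8, tab-separated, header required, decimal point.
Writers use a fixed float format so reruns are byte-identical; every
table round-trips through its own reader without loss at that
precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_vial_table",
    "read_plfa_table",
    "read_table",
    "write_table",
]

FLOAT_FORMAT = "%.12g"

VIAL_COLUMNS = [
    "vial_id", "treatment", "day",
    "gas_conc", "gas_delta", "water_conc", "water_delta",
]
PLFA_COLUMNS = ["vial_id", "treatment", "day", "plfa", "conc", "delta"]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def _validated(df: pd.DataFrame, required: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")
    return df


def read_vial_table(path) -> pd.DataFrame:
    """Per-vial two-phase CO₂ measurement table."""
    return _validated(read_table(path), VIAL_COLUMNS, "vial measurement table")


def read_plfa_table(path) -> pd.DataFrame:
    """Long per-vial PLFA table (one row per vial × PLFA)."""
    return _validated(read_table(path), PLFA_COLUMNS, "PLFA table")
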