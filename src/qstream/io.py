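"""Delimited-text readers/writers for phenotype and survival tables.

Phenotype and survival data live in plain CSV with fixed headers; run
configurations are YAML or JSON documents.  Readers validate row by row and
report malformed rows with their line numbers (header is line 1), so a bad
record in a large field table is locatable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PHENOTYPE_COLUMNS",
    "SURVIVAL_COLUMNS",
    "TableValidationError",
    "read_phenotypes",
    "write_phenotypes",
    "read_survival",
    "write_survival",
    "load_structured",
    "validate_phenotypes",
    "validate_survival",
]

PHENOTYPE_COLUMNS = [
    "individual_id",
    "cross_id",
    "population",
    "stream",
    "experiment",
    "length",
]

SURVIVAL_COLUMNS = [
    "cross_id",
    "population",
    "stream",
    "n_stocked",
    "n_recaptured",
]


class TableValidationError(ValueError):
    """One or more malformed rows; ``errors`` lists (line_number, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        extra = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"invalid table rows: {lines}{extra}")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def validate_phenotypes(df: pd.DataFrame, first_data_line: int = 2) -> None:
    """Check field types and invariants; raise TableValidationError on bad rows."""
    errors: list[tuple[int, str]] = []
    length = pd.to_numeric(df["length"], errors="coerce")
    for i, (val, raw) in enumerate(zip(length, df["length"])):
        if np.isnan(val):
            errors.append((first_data_line + i, f"non-numeric length {raw!r}"))
        elif val <= 0:
            errors.append((first_data_line + i, f"non-positive length {val}"))
    exp = pd.to_numeric(df["experiment"], errors="coerce")
    for i, val in enumerate(exp):
        if val not in (1, 2):
            errors.append((first_data_line + i, f"experiment must be 1 or 2, got {val}"))
    if errors:
        raise TableValidationError(errors)


def validate_survival(df: pd.DataFrame, first_data_line: int = 2) -> None:
    errors: list[tuple[int, str]] = []
    stocked = pd.to_numeric(df["n_stocked"], errors="coerce")
    recap = pd.to_numeric(df["n_recaptured"], errors="coerce")
    for i, (ns, nr) in enumerate(zip(stocked, recap)):
        ln = first_data_line + i
        if np.isnan(ns) or np.isnan(nr):
            errors.append((ln, "non-numeric count"))
        elif ns < 0 or nr < 0:
            errors.append((ln, f"negative count (n_stocked={ns}, n_recaptured={nr})"))
        elif nr > ns:
            errors.append((ln, f"n_recaptured {int(nr)} exceeds n_stocked {int(ns)}"))
    if errors:
        raise TableValidationError(errors)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV into a validated DataFrame.

    Columns: individual_id, cross_id, population, stream, experiment, length.
    An empty file with a header yields an empty table.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "cross_id": str,
                                  "population": str, "stream": str})
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    validate_phenotypes(df)
    df = df[PHENOTYPE_COLUMNS].copy()
    df["experiment"] = df["experiment"].astype(int)
    df["length"] = df["length"].astype(float)
    return df


def write_phenotypes(table: pd.DataFrame, path) -> None:
    _require_columns(table, PHENOTYPE_COLUMNS, path)
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_survival(path) -> pd.DataFrame:
    """Read a per-family survival CSV (eggs stocked, juveniles recaptured)."""
    df = pd.read_csv(path, dtype={"cross_id": str, "population": str, "stream": str})
    _require_columns(df, SURVIVAL_COLUMNS, path)
    validate_survival(df)
    df = df[SURVIVAL_COLUMNS].copy()
    df["n_stocked"] = df["n_stocked"].astype(int)
    df["n_recaptured"] = df["n_recaptured"].astype(int)
    return df


def write_survival(table: pd.DataFrame, path) -> None:
    _require_columns(table, SURVIVAL_COLUMNS, path)
    table[SURVIVAL_COLUMNS].to_csv(path, index=False)


def load_structured(path) -> dict:
    """Load a YAML or JSON configuration document into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return doc
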