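"""Delimited-text formats for response matrices, item tables and configs.

All files are comma-separated UTF-8 with decimal points; a header row is
optional and auto-detected.  Responses may be coded 0/1 or with the
spreadsheet convention 1 = "no" / 2 = "yes" (converted to 0/1 on read).
Missing cells (empty or NA) mark items not administered.  Item and person
indices are 0-based in memory and 1-based in every emitted table.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .banks import ResponseMatrix

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_item_params",
    "write_item_params",
    "load_config",
    "RunConfig",
]

_NA_STRINGS = {"", "na", "nan", "null", "."}

ITEM_PARAM_COLUMNS = ["alpha_pp", "beta_pp", "alpha_cat", "beta_cat"]


def _read_rect(path) -> tuple[list[list[str]], bool]:
    """Tokenize a CSV, enforce rectangularity, detect a header row."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise ValueError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (field counts {sorted(widths)})")

    def _numeric_or_na(tok: str) -> bool:
        t = tok.strip()
        if t.lower() in _NA_STRINGS:
            return True
        try:
            float(t)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric_or_na(tok) for tok in rows[0])
    return rows, has_header


def read_response_matrix(path, coding: str = "01") -> ResponseMatrix:
    """Read a persons x items response file.

    ``coding='01'`` expects cells in {0, 1}; ``coding='12'`` expects the
    1 = "no" / 2 = "yes" convention and maps it to 0/1.  Empty or NA cells
    become masked (unobserved) entries.
    """
    if coding not in ("01", "12"):
        raise ValueError("coding must be '01' or '12'")
    rows, has_header = _read_rect(path)
    body = rows[1:] if has_header else rows
    if not body:
        raise ValueError(f"{path}: no data rows")
    n, j = len(body), len(body[0])
    values = np.zeros((n, j), dtype=np.uint8)
    mask = np.zeros((n, j), dtype=bool)
    allowed = {0.0, 1.0} if coding == "01" else {1.0, 2.0}
    for i, row in enumerate(body):
        for k, tok in enumerate(row):
            t = tok.strip()
            if t.lower() in _NA_STRINGS:
                continue
            v = float(t)
            if v not in allowed:
                raise ValueError(
                    f"{path}: value {t!r} at row {i + 1} outside coding set {sorted(allowed)}"
                )
            values[i, k] = int(v) - (1 if coding == "12" else 0)
            mask[i, k] = True
    return ResponseMatrix(values=values, mask=mask)


def write_response_matrix(rm: ResponseMatrix, path, coding: str = "01", header: bool = True):
    """Write a response matrix; unobserved cells are left empty."""
    if coding not in ("01", "12"):
        raise ValueError("coding must be '01' or '12'")
    offset = 1 if coding == "12" else 0
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow([f"item{k + 1}" for k in range(rm.n_items)])
        for i in range(rm.n_persons):
            w.writerow(
                [
                    str(int(rm.values[i, k]) + offset) if rm.mask[i, k] else ""
                    for k in range(rm.n_items)
                ]
            )


def read_item_params(path) -> pd.DataFrame:
    """Read the 4-column item-parameter table.

    Columns: estimated P&P discrimination and difficulty, then the
    CAT-generating discrimination and difficulty (row order = item order).
    """
    rows, has_header = _read_rect(path)
    body = rows[1:] if has_header else rows
    if not body:
        raise ValueError(f"{path}: no data rows")
    if len(body[0]) != 4:
        raise ValueError(f"{path}: expected 4 columns, found {len(body[0])}")
    try:
        data = np.array([[float(tok) for tok in row] for row in body], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in item-parameter table") from exc
    return pd.DataFrame(data, columns=ITEM_PARAM_COLUMNS)


def write_item_params(table, path):
    """Write the 4-column item-parameter table (header row included)."""
    df = pd.DataFrame(table)
    if list(df.columns) != ITEM_PARAM_COLUMNS:
        if df.shape[1] != 4:
            raise ValueError("item-parameter table must have 4 columns")
        df.columns = ITEM_PARAM_COLUMNS
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Study configuration: condition grid, sizes, seeds and MCMC overrides."""

    conditions: list = field(default_factory=list)  # dicts of condition fields
    n_reps: int = 10
    n_items: int = 100
    n_pp: int = 500
    n_cat: int = 3000
    test_length: int = 30
    n_chains: int = 3
    burn_in: int = 1000
    keep: int = 500
    min_usage: int = 50

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_config(path) -> dict:
    """Load a JSON or YAML configuration file (by extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
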