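"""Tidy-CSV persistence and schema validation for trial tables.

The on-disk format is UTF-8 CSV with a fixed header and column order
(see ``TRIAL_COLUMNS``); absent measurements are empty fields. Reading
validates the schema and value ranges and reports offending rows by
number (1-based, excluding the header). Ground-truth generating
parameters and flat key-value configs use a simple ``key = value`` text
format so every run is reproducible from its artifacts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from corrmem.simulate import TRIAL_COLUMNS

__all__ = ["write_dataset", "read_dataset", "write_config", "read_config"]

_PHASES = {"P1_FAMILIARITY", "P1_ACCURACY", "P2_DETECTION", "P3_TEST"}
_CONDITIONS = {"AFFIRMED_REAL", "CORRECTED_1X", "CORRECTED_3X", "FILLER"}
_CHOICES = {"REAL", "FAKE", "NOVEL"}
_RETRIEVED = {"CORRECT_FAKE", "OTHER", "NOT_ASKED"}

_INT_COLS = ["presentation_index", "rating", "detect_yes",
             "p3_accuracy_rating", "remember_yes"]


class SchemaError(ValueError):
    """Raised when a trial table violates the documented schema."""


def _bad_rows(mask: pd.Series, message: str) -> None:
    mask = mask.fillna(False).astype(bool)
    if mask.any():
        rows = (np.flatnonzero(mask.to_numpy()) + 1)[:10].tolist()
        raise SchemaError(f"{message} (rows {rows})")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, ranges, and structural invariants; return the table."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    t = trials[TRIAL_COLUMNS].copy()
    for col in _INT_COLS:
        t[col] = pd.to_numeric(t[col], errors="coerce").astype("Int64")

    _bad_rows(~t["phase"].isin(_PHASES), "unknown phase value")
    _bad_rows(~t["condition"].isin(_CONDITIONS), "unknown condition value")
    for col in ("rating", "p3_accuracy_rating"):
        vals = t[col].dropna()
        _bad_rows(t[col].notna() & ~t[col].between(1, 6),
                  f"{col} outside [1, 6]")
        del vals
    for col in ("detect_yes", "remember_yes"):
        _bad_rows(t[col].notna() & ~t[col].isin([0, 1]),
                  f"{col} outside {{0, 1}}")
    p3 = t["phase"] == "P3_TEST"
    _bad_rows(p3 & ~t["p3_choice"].isin(_CHOICES), "invalid p3_choice")
    _bad_rows(p3 & ~t["fake_retrieved"].isin(_RETRIEVED),
              "invalid fake_retrieved")
    # gated question flow: the fake-identification question is asked
    # exactly when the correction was reported remembered
    _bad_rows(p3 & (t["remember_yes"] == 0)
              & (t["fake_retrieved"] != "NOT_ASKED"),
              "fake_retrieved present although remember_yes = 0")
    _bad_rows(p3 & (t["remember_yes"] == 1)
              & (t["fake_retrieved"] == "NOT_ASKED"),
              "fake_retrieved NOT_ASKED although remember_yes = 1")
    dup = t.loc[p3].duplicated(subset=["participant_id", "topic_id"])
    if dup.any():
        raise SchemaError(
            f"duplicate (participant, topic) pairs in P3_TEST "
            f"({int(dup.sum())} rows)")
    return t


def write_dataset(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated trial table as UTF-8 CSV with fixed column order."""
    path = Path(path)
    t = validate_trials(trials)
    path.parent.mkdir(parents=True, exist_ok=True)
    t.to_csv(path, index=False, encoding="utf-8")
    return path


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    t = pd.read_csv(path, dtype={"participant_id": str}, encoding="utf-8")
    return validate_trials(t)


def write_config(mapping: dict, path: str | Path) -> Path:
    """Write a flat ``key = value`` text config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{i}: expected 'key = value'")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
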