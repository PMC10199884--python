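"""CSV readers/writers with schema validation, and the run manifest.

Euro amounts are written as two-decimal strings so that a write-read
round trip reproduces the table exactly.  Readers validate enum
membership and numeric domains and report the offending row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .errors import SchemaError

__all__ = ["write_insurees", "read_insurees", "write_assessments",
           "read_assessments", "write_claims", "read_claims",
           "read_tables", "write_manifest"]


def _check_columns(df: pd.DataFrame, expected, name: str) -> None:
    if tuple(df.columns) != tuple(expected):
        raise SchemaError(
            f"{name}: expected columns {list(expected)}, got {list(df.columns)}")


def _check_enum(df: pd.DataFrame, col: str, allowed, name: str) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{name} row {row} column {col}: unknown value "
            f"{df[col].iloc[row]!r} (allowed: {sorted(allowed)})")


def _check_numeric(df: pd.DataFrame, col: str, name: str, minimum=None) -> None:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{name} row {row} column {col}: not a number "
            f"({df[col].iloc[row]!r})")
    if minimum is not None and (values < minimum).any():
        row = int(np.flatnonzero((values < minimum).to_numpy())[0])
        raise SchemaError(
            f"{name} row {row} column {col}: value {values.iloc[row]} "
            f"below minimum {minimum}")


def write_insurees(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(schema.INSUREE_COLUMNS)].copy()
    out["history_premalignancy"] = out["history_premalignancy"].astype(bool)
    out.to_csv(path, index=False)


def read_insurees(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sex": str, "ses": str, "arm": str})
    name = Path(path).name
    _check_columns(df, schema.INSUREE_COLUMNS, name)
    if len(df) == 0:
        return df
    _check_numeric(df, "age", name, minimum=18)
    _check_numeric(df, "n_comorbidities", name, minimum=0)
    _check_enum(df, "sex", schema.SEXES, name)
    _check_enum(df, "ses", schema.SES_LEVELS, name)
    _check_enum(df, "arm", schema.ARMS, name)
    df["history_premalignancy"] = df["history_premalignancy"].astype(bool)
    return df


def write_assessments(df: pd.DataFrame, path) -> None:
    df.loc[:, list(schema.ASSESSMENT_COLUMNS)].to_csv(path, index=False)


def read_assessments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cnn_result": str, "telederm_result": str})
    name = Path(path).name
    _check_columns(df, schema.ASSESSMENT_COLUMNS, name)
    if len(df) == 0:
        return df
    _check_enum(df, "cnn_result", schema.CNN_RESULTS, name)
    _check_enum(df, "telederm_result", schema.TELEDERM_RESULTS, name)
    bad = (df["cnn_result"] == "failed") & (df["telederm_result"] != "none")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{name} row {row} column telederm_result: failed assessments "
            "cannot carry a teledermatologist rating")
    return df


def write_claims(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(schema.CLAIM_COLUMNS)].copy()
    out["cost"] = out["cost"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"category": str, "intervention": str,
                                  "setting": str})
    name = Path(path).name
    _check_columns(df, schema.CLAIM_COLUMNS, name)
    if len(df) == 0:
        df["cost"] = df.get("cost", pd.Series(dtype=float)).astype(float)
        return df
    _check_enum(df, "category", schema.CATEGORIES, name)
    _check_enum(df, "intervention", schema.INTERVENTIONS, name)
    _check_enum(df, "setting", schema.SETTINGS, name)
    _check_numeric(df, "cost", name, minimum=0.0)
    bad = df["setting"] != df["intervention"].map(schema.INTERVENTION_SETTING)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{name} row {row} column setting: inconsistent with "
            f"intervention {df['intervention'].iloc[row]!r}")
    df["cost"] = df["cost"].astype(float)
    return df


def read_tables(insurees_path, assessments_path, claims_path):
    """Read and validate the three pipeline tables."""
    return (read_insurees(insurees_path),
            read_assessments(assessments_path),
            read_claims(claims_path))


def write_manifest(path, seed: int, config_hash: str, stages: dict) -> None:
    """Record seed, config hash, package versions and stage record counts."""
    import dermclaims

    payload = {
        "seed": int(seed),
        "config_hash": config_hash,
        "versions": {
            "dermclaims": dermclaims.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": stages,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
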