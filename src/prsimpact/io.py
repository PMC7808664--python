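"""CSV/YAML/JSON readers and writers for the pipeline's tables and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import COHORT_COLUMNS, CAUSES

__all__ = [
    "read_cohort", "write_cohort",
    "read_incidence_table", "write_incidence_table",
    "read_population_structure", "write_population_structure",
    "read_config", "write_config",
    "write_report",
    "TableFormatError",
]

REPORT_SCHEMA_VERSION = 1

_OUTCOME_LABELS = ("none",) + CAUSES

_NUMERIC_COHORT = ("age", "sbp", "tc", "hdl", "ldl", "ln_crp",
                   "prs_chd", "prs_stroke", "follow_up")
_INT_COHORT = ("id", "centre", "smoker", "diabetes")


class TableFormatError(ValueError):
    """Raised for malformed tabular inputs, naming the offending rows."""


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    if df.empty:
        raise TableFormatError(f"{what} table is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{what} table lacks required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        import warnings
        warnings.warn(f"{what} table has unknown columns {extra}; ignored")


def _coerce_numeric(df: pd.DataFrame, cols, what: str) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise TableFormatError(
                f"non-numeric value in column {c!r} of {what} table "
                f"at line(s) {lines}")
        if coerced.isna().any():
            lines = (df.index[coerced.isna()] + 2).tolist()[:5]
            raise TableFormatError(
                f"missing value in column {c!r} of {what} table at line(s) {lines}")
        df[c] = coerced
    return df


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sex": str, "outcome": str})
    _check_columns(df, COHORT_COLUMNS, "cohort")
    df = _coerce_numeric(df, _NUMERIC_COHORT + _INT_COHORT, "cohort")
    for c in _INT_COHORT:
        df[c] = df[c].astype(np.int64)
    bad = ~df["outcome"].isin(_OUTCOME_LABELS)
    if bad.any():
        raise TableFormatError(
            f"unknown outcome label at line(s) {(df.index[bad] + 2).tolist()[:5]}")
    if (df["follow_up"] <= 0).any():
        raise TableFormatError("follow_up must be positive")
    return df[list(COHORT_COLUMNS)]


def write_cohort(df: pd.DataFrame, path) -> None:
    df[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_incidence_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sex": str, "cause": str})
    _check_columns(df, ("age_lo", "age_hi", "sex", "cause", "rate"), "incidence")
    df = _coerce_numeric(df, ("age_lo", "age_hi", "rate"), "incidence")
    if (df["rate"] < 0).any():
        raise TableFormatError("incidence rates must be non-negative")
    # bands within a sex x cause series must not overlap
    for (cause, s), grp in df.groupby(["cause", "sex"]):
        g = grp.sort_values("age_lo")
        if (g["age_lo"].to_numpy()[1:] < g["age_hi"].to_numpy()[:-1] - 1e-9).any():
            raise TableFormatError(f"overlapping age bands for ({cause}, {s})")
    return df


def write_incidence_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_population_structure(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sex": str})
    _check_columns(df, ("age_lo", "age_hi", "sex", "count"), "population structure")
    df = _coerce_numeric(df, ("age_lo", "age_hi", "count"), "population structure")
    if (df["count"] < 0).any():
        raise TableFormatError("population counts must be non-negative")
    if df["count"].sum() <= 0:
        raise TableFormatError("population structure total must be positive")
    df["count"] = df["count"].astype(np.int64)
    return df


def write_population_structure(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def write_report(report: dict, path) -> None:
    """Deterministic JSON report (sorted keys, schema version stamped)."""
    payload = dict(report)
    payload["schema_version"] = REPORT_SCHEMA_VERSION
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(payload), fh, sort_keys=True, indent=2)
        fh.write("\n")
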