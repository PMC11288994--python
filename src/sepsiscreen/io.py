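"""CSV schema (versioned) for case, outcome, resolved-vitals and panel
tables, plus the run manifest.

All tables are UTF-8 CSV with a header row; missing values are empty fields;
booleans are written as ``true``/``false``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import SCHEMA_VERSION, __version__
from .vitals import VITALS

_SLOT_NUMERIC = [f"{v}_{s}" for v in ("rr", "spo2", "sbp", "hr", "temp", "gcs") for s in (1, 2)]
_SLOT_BOOL = [f"on_oxygen_{s}" for s in (1, 2)]
_SLOT_STR = [f"consciousness_{s}" for s in (1, 2)]

CASES_COLUMNS = (
    ["case_id", "age", "sex", "staff", "transported", "suspicion_documented"]
    + _SLOT_NUMERIC
    + _SLOT_BOOL
    + _SLOT_STR
)
OUTCOMES_COLUMNS = ["case_id", "sepsis", "mi", "stroke", "died_in_hospital", "death_day"]

_BOOL_TRUE = "true"
_BOOL_FALSE = "false"


def _encode_bools(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        if col in out.columns:
            out[col] = out[col].map(
                lambda x: "" if pd.isna(x) else (_BOOL_TRUE if bool(x) else _BOOL_FALSE)
            )
    return out


def _decode_bool(series: pd.Series, nullable: bool) -> pd.Series:
    mapped = series.map({_BOOL_TRUE: True, _BOOL_FALSE: False, "": pd.NA})
    if nullable:
        return mapped.astype("boolean")
    if mapped.isna().any():
        raise ValueError(f"column {series.name!r}: unexpected missing boolean")
    return mapped.astype(bool)


def write_cases(cases: pd.DataFrame, path) -> None:
    df = cases.reindex(columns=CASES_COLUMNS)
    df = _encode_bools(df, ["transported", "suspicion_documented"] + _SLOT_BOOL)
    df.to_csv(path, index=False, na_rep="")


def read_cases(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CASES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cases file lacks columns: {sorted(missing)}")
    out = pd.DataFrame({"case_id": df["case_id"]})
    out["age"] = pd.to_numeric(df["age"].replace("", np.nan))
    out["sex"] = df["sex"]
    out["staff"] = df["staff"]
    out["transported"] = _decode_bool(df["transported"], nullable=False)
    out["suspicion_documented"] = _decode_bool(df["suspicion_documented"], nullable=False)
    for col in _SLOT_NUMERIC:
        out[col] = pd.to_numeric(df[col].replace("", np.nan))
    for col in _SLOT_BOOL:
        out[col] = _decode_bool(df[col], nullable=True)
    for col in _SLOT_STR:
        out[col] = df[col].replace("", None)
    return out


def write_outcomes(outcomes: pd.DataFrame, path) -> None:
    df = outcomes.reindex(columns=OUTCOMES_COLUMNS)
    df = _encode_bools(df, ["sepsis", "mi", "stroke", "died_in_hospital"])
    df.to_csv(path, index=False, na_rep="")


def read_outcomes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(OUTCOMES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outcomes file lacks columns: {sorted(missing)}")
    out = pd.DataFrame({"case_id": df["case_id"]})
    for col in ("sepsis", "mi", "stroke", "died_in_hospital"):
        out[col] = _decode_bool(df[col], nullable=False)
    out["death_day"] = pd.to_numeric(df["death_day"].replace("", np.nan))
    return out


def write_resolved(resolved: pd.DataFrame, path) -> None:
    df = _encode_bools(resolved, ["on_oxygen", "excluded"])
    df.to_csv(path, index=False, na_rep="")


def read_resolved(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = pd.DataFrame({"case_id": df["case_id"]})
    out["age"] = pd.to_numeric(df["age"].replace("", np.nan))
    out["staff"] = df["staff"]
    for vital in ("rr", "spo2", "sbp", "hr", "temp", "gcs"):
        out[vital] = pd.to_numeric(df[vital].replace("", np.nan))
        out[f"{vital}_src"] = df[f"{vital}_src"]
    out["on_oxygen"] = _decode_bool(df["on_oxygen"], nullable=True)
    out["on_oxygen_src"] = df["on_oxygen_src"]
    out["consciousness"] = df["consciousness"].replace("", None)
    out["consciousness_src"] = df["consciousness_src"]
    if "excluded" in df.columns:
        out["excluded"] = _decode_bool(df["excluded"], nullable=False)
    return out


def write_panel(panel: pd.DataFrame, path) -> None:
    df = _encode_bools(
        panel, [f"{t}_pos" for t in ("qsofa", "sirs", "mews", "news2")] + ["excluded"]
    )
    df.to_csv(path, index=False, na_rep="")


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = pd.DataFrame({"case_id": df["case_id"]})
    if "strategy" in df.columns:
        out["strategy"] = df["strategy"]
    for tool in ("qsofa", "sirs", "mews", "news2"):
        out[tool] = pd.to_numeric(df[tool].replace("", np.nan)).astype("Int64")
        out[f"{tool}_pos"] = _decode_bool(df[f"{tool}_pos"], nullable=True)
    if "excluded" in df.columns:
        out["excluded"] = _decode_bool(df["excluded"], nullable=False)
    return out


def config_hash(config_dict: dict) -> str:
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(path, config_dict: dict, seed: int, outputs: list[str], extra: dict | None = None) -> None:
    manifest = {
        "package": "sepsiscreen",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "outputs": sorted(outputs),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
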