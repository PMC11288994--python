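"""The four prehospital-adapted screening-score calculators.

All calculators assume a missing-data strategy has already been applied: a
required vital that is still missing raises :class:`MissingVitalError` naming
the vital. Mentation handling follows the prehospital adaptation: qSOFA
scores "altered mentation" from the GCS when documented, falling back to the
ACVPU category; MEWS and NEWS2 use the ACVPU category, falling back to a
GCS-derived one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MissingVitalError
from .tables import TOOLS, ScoreTable, default_tables
from ._round import quantize
from .vitals import Vitals, gcs_to_acvpu

__all__ = [
    "qsofa",
    "sirs_prehospital",
    "mews_prehospital",
    "news2",
    "screen_positive",
    "score_panel",
    "TOOLS",
]


def _is_missing(value) -> bool:
    if value is None:
        return True
    if value is pd.NA:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


def _mentation(v: Vitals, prefer: str, tool: str):
    """Return (gcs, consciousness) with the preferred channel resolved.

    ``prefer`` is "gcs" (qSOFA) or "acvpu" (MEWS/NEWS2); the other channel
    serves as fallback. Raises when both are missing.
    """
    gcs_ok = not _is_missing(v.gcs)
    con_ok = not _is_missing(v.consciousness)
    if not gcs_ok and not con_ok:
        raise MissingVitalError("gcs" if prefer == "gcs" else "consciousness", tool)
    if prefer == "gcs":
        if gcs_ok:
            return ("gcs", v.gcs)
        return ("acvpu", v.consciousness)
    if con_ok:
        return ("acvpu", v.consciousness)
    return ("acvpu", gcs_to_acvpu(quantize([v.gcs])[0]))


def _component_score(table: ScoreTable, vital: str, value, tool: str) -> int:
    if _is_missing(value):
        raise MissingVitalError(vital, tool)
    return table.components[vital].lookup(value)


def qsofa(v: Vitals, tables=None) -> int:
    """qSOFA, 0-3: rr >= 22, sbp <= 100, altered mentation (GCS < 15)."""
    table = (tables or default_tables())["qsofa"]
    pts = _component_score(table, "rr", v.rr, "qsofa")
    pts += _component_score(table, "sbp", v.sbp, "qsofa")
    channel, value = _mentation(v, "gcs", "qsofa")
    if channel == "gcs":
        pts += table.components["gcs"].lookup(value)
    else:
        pts += 0 if value == "A" else 1
    return int(pts)


def sirs_prehospital(v: Vitals, tables=None) -> int:
    """Prehospital SIRS, 0-3: temperature, heart rate and respiratory rate
    criteria only (leukocyte count and paCO2 arms omitted)."""
    table = (tables or default_tables())["sirs"]
    return int(sum(_component_score(table, vit, v.get(vit), "sirs") for vit in table.components))


def mews_prehospital(v: Vitals, tables=None) -> int:
    """Prehospital MEWS, 0-14: sbp, hr, rr, temperature and AVPU (urine
    output omitted). Documented new confusion ("C") scores as "V"."""
    table = (tables or default_tables())["mews"]
    pts = 0
    for vit, comp in table.components.items():
        if vit == "consciousness":
            _, value = _mentation(v, "acvpu", "mews")
            pts += comp.lookup(value)
        else:
            pts += _component_score(table, vit, v.get(vit), "mews")
    return int(pts)


def news2(v: Vitals, tables=None) -> int:
    """NEWS2, 0-20, SpO2 scale 1 only (no hypercapnic-failure designation in
    EMS records): rr, spo2, supplemental oxygen, sbp, hr, ACVPU, temperature."""
    table = (tables or default_tables())["news2"]
    pts = 0
    for vit, comp in table.components.items():
        if vit == "consciousness":
            _, value = _mentation(v, "acvpu", "news2")
            pts += comp.lookup(value)
        else:
            pts += _component_score(table, vit, v.get(vit), "news2")
    return int(pts)


_CALCULATORS = {
    "qsofa": qsofa,
    "sirs": sirs_prehospital,
    "mews": mews_prehospital,
    "news2": news2,
}


def compute_score(tool: str, v: Vitals, tables=None) -> int:
    if tool not in _CALCULATORS:
        raise ValueError(f"unknown screening tool: {tool!r}")
    return _CALCULATORS[tool](v, tables=tables)


def screen_positive(tool: str, score: int, tables=None) -> bool:
    """Positivity at the recommended thresholds: qSOFA/SIRS >= 2, MEWS >= 4,
    NEWS2 >= 5."""
    tabs = tables or default_tables()
    if tool not in tabs:
        raise ValueError(f"unknown screening tool: {tool!r}")
    if _is_missing(score):
        raise ValueError(f"{tool}: score undefined, cannot judge positivity")
    return bool(score >= tabs[tool].threshold)


# ---------------------------------------------------------------------------
# vectorised panel computation


def _mentation_arrays(df: pd.DataFrame):
    gcs = df["gcs"].to_numpy(dtype=float)
    con = df["consciousness"].astype(object).to_numpy()
    con = np.array([None if _is_missing(c) else str(c) for c in con], dtype=object)
    gcs_ok = ~np.isnan(gcs)
    con_ok = np.array([c is not None for c in con])
    if not np.all(gcs_ok | con_ok):
        raise MissingVitalError("consciousness")
    # ACVPU channel with GCS fallback
    acvpu = con.copy()
    fb = ~con_ok
    if fb.any():
        acvpu[fb] = [gcs_to_acvpu(g) for g in quantize(gcs[fb])]
    # altered-mentation indicator, GCS preferred
    altered = np.where(gcs_ok, quantize(np.where(gcs_ok, gcs, 15.0)) < 15, acvpu != "A")
    return acvpu, altered.astype(int)


def _numeric_column(df: pd.DataFrame, vital: str) -> np.ndarray:
    if vital == "on_oxygen":
        col = df[vital]
        if col.isna().any():
            raise MissingVitalError("on_oxygen")
        return col.to_numpy(dtype=bool)
    arr = df[vital].to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise MissingVitalError(vital)
    return arr


def score_panel(resolved: pd.DataFrame, strategy: str = "", tables=None) -> pd.DataFrame:
    """Compute all four scores and positivity flags for a resolved cohort.

    Rows flagged ``excluded`` (complete-case strategy) receive undefined
    scores/flags (``NA``); all other rows must have every required vital
    present.
    """
    tabs = tables or default_tables()
    n = len(resolved)
    excluded = (
        resolved["excluded"].to_numpy(dtype=bool)
        if "excluded" in resolved.columns
        else np.zeros(n, dtype=bool)
    )
    panel = pd.DataFrame({"case_id": resolved["case_id"].to_numpy()})
    if strategy:
        panel["strategy"] = strategy

    sub = resolved.loc[~excluded]
    scores: dict[str, np.ndarray] = {}
    if len(sub):
        acvpu, altered = _mentation_arrays(sub)
        for tool in TOOLS:
            table = tabs[tool]
            total = np.zeros(len(sub), dtype=int)
            for vit, comp in table.components.items():
                if vit == "consciousness":
                    total += comp.lookup_array(acvpu)
                elif tool == "qsofa" and vit == "gcs":
                    total += altered
                else:
                    total += comp.lookup_array(_numeric_column(sub, vit))
            scores[tool] = total
    for tool in TOOLS:
        col = pd.array([pd.NA] * n, dtype="Int64")
        flag = pd.array([pd.NA] * n, dtype="boolean")
        if len(sub):
            col[~excluded] = scores[tool]
            flag[~excluded] = scores[tool] >= tabs[tool].threshold
        panel[tool] = col
        panel[f"{tool}_pos"] = flag
    panel["excluded"] = excluded
    return panel
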