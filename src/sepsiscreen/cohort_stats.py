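"""Cohort epidemiology: incidence, case fatality, documentation completeness
and sepsis-suspicion rates."""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd

from .accuracy import Proportion, chi2_cramers_v, proportion
from .vitals import DOCUMENTED_VARIABLES

__all__ = [
    "incidence",
    "case_fatality",
    "completeness_table",
    "suspicion_rate",
    "documented_mask",
]

CONDITIONS = ("sepsis", "mi", "stroke")


def incidence(outcomes: pd.DataFrame, condition: str) -> Proportion:
    """Diagnosed cases over all cases, with Wilson CI."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition: {condition!r}")
    n = len(outcomes)
    if n == 0:
        raise ValueError("empty cohort")
    k = int(outcomes[condition].sum())
    return proportion(k, n)


def case_fatality(
    outcomes: pd.DataFrame,
    condition: str,
    window: Literal["hospital", "30d"] = "30d",
) -> Proportion:
    """Deaths within the window among diagnosed cases.

    The 30-day window counts deaths with ``death_day <= 30``, day 0 being the
    day of EMS contact.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition: {condition!r}")
    sel = outcomes.loc[outcomes[condition].astype(bool)]
    n = len(sel)
    if n == 0:
        raise ValueError(f"no diagnosed {condition} cases")
    if window == "hospital":
        deaths = int(sel["died_in_hospital"].sum())
    elif window == "30d":
        dd = pd.to_numeric(sel["death_day"], errors="coerce")
        deaths = int((dd <= 30).sum())
    else:
        raise ValueError(f"unknown window: {window!r}")
    return proportion(deaths, n)


def documented_mask(cases: pd.DataFrame, variable: str) -> np.ndarray:
    """True where at least one assessment slot carries a value."""
    return (
        cases[f"{variable}_1"].notna() | cases[f"{variable}_2"].notna()
    ).to_numpy()


def completeness_table(
    cases: pd.DataFrame,
    group_by: Literal["staff", "sepsis_label"] = "staff",
    outcomes: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-variable documentation rates by group, with chi-square/Cramer's V.

    A variable counts as documented when either slot is filled. Output has
    one row per variable plus an ``all_documented`` row (every variable
    filled), columns per group (rate, Wilson CI, n) and the association test
    across groups.
    """
    if group_by == "staff":
        groups = cases["staff"].astype(str)
        group_values = sorted(groups.unique())
    elif group_by == "sepsis_label":
        if outcomes is None:
            raise ValueError("sepsis_label grouping requires the outcomes table")
        merged = cases.merge(outcomes[["case_id", "sepsis"]], on="case_id", how="inner")
        if len(merged) != len(cases):
            raise ValueError("outcomes table does not cover all cases")
        cases = merged
        groups = np.where(cases["sepsis"].to_numpy(dtype=bool), "sepsis", "no_sepsis")
        groups = pd.Series(groups, index=cases.index)
        group_values = ["sepsis", "no_sepsis"]
    else:
        raise ValueError(f"unknown grouping: {group_by!r}")
    if any((groups == g).sum() == 0 for g in group_values) or len(group_values) < 2:
        raise ValueError("each group must be non-empty and at least two groups present")

    docs = {var: documented_mask(cases, var) for var in DOCUMENTED_VARIABLES}
    docs["all_documented"] = np.logical_and.reduce(list(docs.values()))

    rows = []
    for var, mask in docs.items():
        row: dict = {"variable": var}
        table = []
        for g in group_values:
            in_g = (groups == g).to_numpy()
            n_g = int(in_g.sum())
            k_g = int(mask[in_g].sum())
            p = proportion(k_g, n_g)
            row[f"rate_{g}"] = p.value
            row[f"ci_low_{g}"] = p.lower
            row[f"ci_high_{g}"] = p.upper
            row[f"n_{g}"] = n_g
            table.append([k_g, n_g - k_g])
        t = np.asarray(table).T  # documented/undocumented x group
        if (t.sum(axis=1) == 0).any():
            chi2, pval, v = 0.0, 1.0, 0.0  # degenerate: all (un)documented
        else:
            chi2, pval, v = chi2_cramers_v(t)
        row.update({"chi2": chi2, "p": pval, "cramers_v": v})
        rows.append(row)
    return pd.DataFrame(rows)


def suspicion_rate(cases: pd.DataFrame, staff: str) -> Proportion:
    """Documented sepsis suspicions over cases in the staff stratum."""
    sel = cases.loc[cases["staff"].astype(str) == staff]
    if len(sel) == 0:
        raise ValueError(f"empty staff stratum: {staff!r}")
    k = int(sel["suspicion_documented"].sum())
    return proportion(k, len(sel))
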