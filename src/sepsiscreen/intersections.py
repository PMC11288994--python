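"""Set-intersection analysis of the four screening tools' positive calls.

Partitions cases into the 16 subsets of {qSOFA, SIRS, MEWS, NEWS2} positives
and evaluates combined any-of-four / all-four rules. Cases with an undefined
flag for any tool (complete-case exclusions) must be dropped upstream so the
denominators stay consistent across tools.
"""

from __future__ import annotations

from itertools import product
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .accuracy import Proportion, proportion
from .tables import TOOLS

__all__ = ["combination_counts", "combined_rule", "unique_positive_share", "TOOLS"]


def _flag_matrix(flags: pd.DataFrame) -> np.ndarray:
    missing = [t for t in TOOLS if t not in flags.columns]
    if missing:
        raise ValueError(f"flag table lacks tool columns: {missing}")
    mat = np.empty((len(flags), 4), dtype=bool)
    for j, tool in enumerate(TOOLS):
        col = flags[tool]
        if col.isna().any():
            raise ValueError(
                f"{tool}: undefined flags present; resolve or drop excluded cases first"
            )
        mat[:, j] = col.to_numpy(dtype=bool)
    return mat


def combination_counts(flags: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Exact partition of cases over the 16 tool-combination subsets.

    ``flags`` needs boolean columns qsofa/sirs/mews/news2; ``labels`` is the
    per-case sepsis label. Returns 16 rows (one per subset, including the
    empty one) with counts and percentages among all cases and among
    label-positive cases.
    """
    mat = _flag_matrix(flags)
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(mat):
        raise ValueError("labels length does not match flag table")
    weights = np.array([8, 4, 2, 1])
    codes = mat @ weights
    n = len(mat)
    n_sep = int(labels.sum())
    rows = []
    for bits in product((False, True), repeat=4):
        code = int(np.dot(np.array(bits), weights))
        in_subset = codes == code
        count_all = int(in_subset.sum())
        count_sep = int((in_subset & labels).sum())
        rows.append(
            {
                "subset": "+".join(t for t, b in zip(TOOLS, bits) if b) or "none",
                **{tool: b for tool, b in zip(TOOLS, bits)},
                "count_all": count_all,
                "pct_all": 100.0 * count_all / n if n else 0.0,
                "count_sepsis": count_sep,
                "pct_sepsis": 100.0 * count_sep / n_sep if n_sep else 0.0,
            }
        )
    return pd.DataFrame(rows)


def unique_positive_share(
    partition: pd.DataFrame, tool: str, among: Literal["all", "sepsis"] = "sepsis"
) -> Proportion:
    """Share of cases flagged by one tool and no other, with Wilson CI.

    ``among="sepsis"`` gives the share of label-positive cases uniquely
    predicted by the tool (the true-positive-only cell).
    """
    if tool not in TOOLS:
        raise ValueError(f"unknown screening tool: {tool!r}")
    mask = np.ones(len(partition), dtype=bool)
    for t in TOOLS:
        want = t == tool
        mask &= partition[t].to_numpy(dtype=bool) == want
    row = partition.loc[mask]
    count_col = "count_sepsis" if among == "sepsis" else "count_all"
    k = int(row[count_col].iloc[0])
    total_col = "count_sepsis" if among == "sepsis" else "count_all"
    n = int(partition[total_col].sum())
    return proportion(k, n)


def combined_rule(flags: pd.DataFrame, mode: Literal["any", "all"]) -> np.ndarray:
    """Logical OR ("any") or AND ("all") across the four tools' flags."""
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    mat = _flag_matrix(flags)
    return mat.any(axis=1) if mode == "any" else mat.all(axis=1)
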