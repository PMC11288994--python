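"""Report assembly: accuracy tables per strategy, completeness tables,
intersection partitions and cohort epidemiology, as data frames and markdown.

Displayed values are rounded half-up at the report precisions: one decimal
for percentages and likelihood ratios, three decimals for AUROC.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from ._round import round_half_up
from .accuracy import AccuracySummary, accuracy_summary, confusion, mcnemar
from .cohort_stats import CONDITIONS, case_fatality, incidence, suspicion_rate
from .intersections import combination_counts, combined_rule
from .tables import TOOLS

RULES = TOOLS + ("any", "all")


def merge_panel_outcomes(panel: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    merged = panel.merge(outcomes[["case_id", "sepsis"]], on="case_id", how="inner")
    if len(merged) != len(panel):
        raise ValueError("outcomes table does not cover every panel case")
    if "excluded" in merged.columns:
        merged = merged.loc[~merged["excluded"].astype(bool)].reset_index(drop=True)
    return merged


def evaluate_panel(panel: pd.DataFrame, outcomes: pd.DataFrame) -> dict[str, AccuracySummary]:
    """Accuracy summaries for each tool and the combined any/all rules.

    Complete-case exclusions are dropped first so all rules share one
    denominator.
    """
    merged = merge_panel_outcomes(panel, outcomes)
    labels = merged["sepsis"].to_numpy(dtype=bool)
    flags = merged[[f"{t}_pos" for t in TOOLS]].rename(
        columns={f"{t}_pos": t for t in TOOLS}
    )
    out: dict[str, AccuracySummary] = {}
    for tool in TOOLS:
        out[tool] = accuracy_summary(confusion(flags[tool].to_numpy(dtype=bool), labels))
    for mode in ("any", "all"):
        out[mode] = accuracy_summary(confusion(combined_rule(flags, mode), labels))
    return out


def _fmt_prop(p, nd=1):
    return f"{p.pct(nd)}% [{round_half_up(100 * p.lower, nd)}; {round_half_up(100 * p.upper, nd)}]"


def accuracy_frame(summaries: dict[str, AccuracySummary]) -> pd.DataFrame:
    """Screening-results table: one column per rule, metric rows."""
    metrics = [
        ("positivity_pct", lambda s: s.positivity_rate.pct()),
        ("sensitivity_pct", lambda s: s.sensitivity.pct()),
        ("specificity_pct", lambda s: s.specificity.pct()),
        ("auroc", lambda s: round_half_up(s.auroc, 3)),
        ("ppv_pct", lambda s: s.ppv.pct() if s.ppv else None),
        ("npv_pct", lambda s: s.npv.pct() if s.npv else None),
        ("lr_plus", lambda s: round_half_up(s.lr_plus, 1) if s.lr_plus != float("inf") else None),
        ("lr_minus", lambda s: round_half_up(s.lr_minus, 1) if s.lr_minus != float("inf") else None),
        ("tp", lambda s: s.cm.tp),
        ("fp", lambda s: s.cm.fp),
        ("fn", lambda s: s.cm.fn),
        ("tn", lambda s: s.cm.tn),
    ]
    data = {rule: [fn(s) for _, fn in metrics] for rule, s in summaries.items()}
    return pd.DataFrame(data, index=[name for name, _ in metrics])


def mcnemar_frame(panel: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise McNemar tests between the four tools' screening results."""
    merged = merge_panel_outcomes(panel, outcomes)
    rows = []
    for a, b in combinations(TOOLS, 2):
        res = mcnemar(
            merged[f"{a}_pos"].to_numpy(dtype=bool),
            merged[f"{b}_pos"].to_numpy(dtype=bool),
        )
        rows.append(
            {
                "tool_a": a,
                "tool_b": b,
                "b_discordant": res.b,
                "c_discordant": res.c,
                "statistic": res.statistic,
                "p": res.pvalue,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def epidemiology_frame(outcomes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:
        inc = incidence(outcomes, cond)
        row = {
            "condition": cond,
            "cases": inc.successes,
            "n": inc.trials,
            "incidence_pct": inc.pct(),
            "incidence_ci_low": round_half_up(100 * inc.lower, 1),
            "incidence_ci_high": round_half_up(100 * inc.upper, 1),
        }
        for window in ("hospital", "30d"):
            try:
                cf = case_fatality(outcomes, cond, window)
                row[f"fatality_{window}_pct"] = cf.pct()
                row[f"deaths_{window}"] = cf.successes
            except ValueError:
                row[f"fatality_{window}_pct"] = None
                row[f"deaths_{window}"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def suspicion_frame(cases: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for staff in sorted(cases["staff"].astype(str).unique()):
        p = suspicion_rate(cases, staff)
        rows.append(
            {
                "staff": staff,
                "suspicions": p.successes,
                "n": p.trials,
                "rate_pct": p.pct(),
                "ci_low_pct": round_half_up(100 * p.lower, 2),
                "ci_high_pct": round_half_up(100 * p.upper, 2),
            }
        )
    return pd.DataFrame(rows)


def intersection_frame(panel: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    merged = merge_panel_outcomes(panel, outcomes)
    flags = merged[[f"{t}_pos" for t in TOOLS]].rename(
        columns={f"{t}_pos": t for t in TOOLS}
    )
    return combination_counts(flags, merged["sepsis"].to_numpy(dtype=bool))


def _df_to_markdown(df: pd.DataFrame, float_dp: int = 3) -> str:
    show = df.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            show[col] = show[col].map(
                lambda x: "" if pd.isna(x) else f"{round_half_up(x, float_dp)}"
            )
    header = "| " + " | ".join(str(c) for c in show.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in show.columns) + "|"
    body = [
        "| " + " | ".join("" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v) for v in row) + " |"
        for row in show.itertuples(index=False)
    ]
    return "\n".join([header, sep] + body)


def markdown_report(
    epidemiology: pd.DataFrame,
    completeness: pd.DataFrame,
    suspicion: pd.DataFrame,
    accuracy_by_strategy: dict[str, pd.DataFrame],
    intersections: pd.DataFrame,
) -> str:
    parts = ["# Synthetic prehospital sepsis-screening study", ""]
    parts += ["## Incidence and case fatality", "", _df_to_markdown(epidemiology), ""]
    parts += ["## Documentation completeness", "", _df_to_markdown(completeness), ""]
    parts += ["## Sepsis-suspicion rates by staff type", "", _df_to_markdown(suspicion), ""]
    for strategy, frame in accuracy_by_strategy.items():
        parts += [
            f"## Screening accuracy — missing-data strategy: {strategy}",
            "",
            _df_to_markdown(frame.reset_index(names="metric")),
            "",
        ]
    parts += ["## Tool intersections (16-way partition)", "", _df_to_markdown(intersections), ""]
    return "\n".join(parts)
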