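"""Turn raw two-slot EMS documentation into one analysis value per vital.

Stages: plausibility filtering (out-of-range values become missing), slot
resolution (a variable counts as documented if either assessment slot is
filled; the first slot wins by default), consciousness derivation (documented
category wins, otherwise mapped from GCS), and one of four missing-data
strategies:

``complete_case``
    exclude the record when any tool-required vital is missing;
``missing_as_normal``
    substitute values that score zero points in every tool;
``hotdeck``
    draw seeded donors from documented records within age-band x staff
    strata (sepsis-blind);
``missing_as_worst``
    substitute the maximal-scoring value of each tool's table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from ._round import quantize
from .errors import ConfigurationError
from .vitals import (
    NORMAL_VALUES,
    NUMERIC_VITALS,
    PLAUSIBILITY_RANGES,
    VITALS,
    WORST_VALUES,
    Vitals,
    gcs_to_acvpu,
)

logger = logging.getLogger(__name__)

STRATEGY_NAMES = ("complete_case", "missing_as_normal", "hotdeck", "missing_as_worst")

#: Short CLI aliases for the strategies.
STRATEGY_ALIASES = {
    "complete_case": "complete_case",
    "normal": "missing_as_normal",
    "missing_as_normal": "missing_as_normal",
    "hotdeck": "hotdeck",
    "hotdeck_imputation": "hotdeck",
    "worst": "missing_as_worst",
    "missing_as_worst": "missing_as_worst",
}

#: Vitals some tool needs; mentation counts as available if either the GCS
#: or the consciousness category is documented.
REQUIRED_VITALS = ("rr", "spo2", "on_oxygen", "sbp", "hr", "temp")


@dataclass(frozen=True)
class PlausibilityRanges:
    """Closed acceptance intervals per numeric vital; GCS must be integer."""

    ranges: dict = field(default_factory=lambda: dict(PLAUSIBILITY_RANGES))

    def __post_init__(self):
        for vital, (lo, hi) in self.ranges.items():
            if vital not in NUMERIC_VITALS:
                raise ConfigurationError(f"ranges: unknown vital {vital!r}")
            if not lo < hi:
                raise ConfigurationError(f"ranges[{vital}]: lower must be < upper")
        missing = set(NUMERIC_VITALS) - set(self.ranges)
        if missing:
            raise ConfigurationError(f"ranges: missing vitals {sorted(missing)}")

    def is_plausible(self, vital: str, value: float) -> bool:
        lo, hi = self.ranges[vital]
        if not (lo <= value <= hi):
            return False
        if vital == "gcs" and float(value) != int(value):
            return False
        return True


DEFAULT_RANGES = PlausibilityRanges()


def plausibility_filter(
    v: Vitals, ranges: PlausibilityRanges = DEFAULT_RANGES
) -> Vitals:
    """Replace out-of-range numeric values by missing; idempotent."""
    updates = {}
    for vital in NUMERIC_VITALS:
        value = v.get(vital)
        if value is not None and not ranges.is_plausible(vital, value):
            updates[vital] = None
    consciousness = v.consciousness
    if consciousness is not None and consciousness not in ("A", "C", "V", "P", "U"):
        updates["consciousness"] = None
    return v.replace(**updates) if updates else v


def filter_frame(
    cases: pd.DataFrame, ranges: PlausibilityRanges = DEFAULT_RANGES
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Plausibility-filter both assessment slots of a cohort table.

    Returns the filtered copy and a per-variable count of removed values.
    """
    out = cases.copy()
    removed: dict[str, int] = {}
    for vital in NUMERIC_VITALS:
        lo, hi = ranges.ranges[vital]
        for slot in (1, 2):
            col = f"{vital}_{slot}"
            if col not in out.columns:
                continue
            vals = out[col].to_numpy(dtype=float)
            bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
            if vital == "gcs":
                bad |= ~np.isnan(vals) & (vals != np.floor(vals))
            if bad.any():
                out.loc[bad, col] = np.nan
            removed[col] = int(bad.sum())
    for slot in (1, 2):
        col = f"consciousness_{slot}"
        if col in out.columns:
            bad = out[col].notna() & ~out[col].isin(["A", "C", "V", "P", "U"])
            out.loc[bad, col] = None
            removed[col] = removed.get(col, 0) + int(bad.sum())
    return out, removed


def resolve_assessment(
    first: Vitals, second: Vitals, precedence: Literal["first", "worst"] = "first"
) -> tuple[Vitals, dict[str, str]]:
    """Collapse two (already filtered) slots into one value per vital.

    Default precedence: the first assessment wins when both are present
    (first-contact values are the screening-relevant ones); ``worst`` picks,
    per vital, the slot scoring more NEWS2 points (GCS: the lower value).
    """
    values = {}
    provenance = {}
    for vital in VITALS:
        a, b = first.get(vital), second.get(vital)
        if a is None and b is None:
            values[vital] = None
            provenance[vital] = "missing"
        elif a is None:
            values[vital] = b
            provenance[vital] = "second"
        elif b is None or precedence == "first":
            values[vital] = a
            provenance[vital] = "first"
        else:
            pick_second = _worse_is_second(vital, a, b)
            values[vital] = b if pick_second else a
            provenance[vital] = "second" if pick_second else "first"
    return Vitals(**values), provenance


def _worse_is_second(vital: str, a, b) -> bool:
    from .tables import default_tables

    if vital == "gcs":
        return b < a
    if vital == "consciousness":
        order = {"A": 0, "C": 1, "V": 1, "P": 2, "U": 3}
        return order[b] > order[a]
    if vital == "on_oxygen":
        return bool(b) and not bool(a)
    comp = default_tables()["news2"].components.get(vital)
    if comp is None:
        return False
    return comp.lookup(b) > comp.lookup(a)


def derive_consciousness(v: Vitals) -> Optional[str]:
    """Documented ACVPU category wins; otherwise map from GCS; else missing."""
    if v.consciousness is not None:
        return v.consciousness
    if v.gcs is not None:
        return gcs_to_acvpu(quantize([v.gcs])[0])
    return None


def resolve_frame(
    cases: pd.DataFrame,
    ranges: PlausibilityRanges = DEFAULT_RANGES,
    precedence: Literal["first", "worst"] = "first",
) -> pd.DataFrame:
    """Filter, slot-resolve and consciousness-derive a whole cohort table.

    Returns one row per case with columns ``case_id, age, staff``, one value
    column per vital, and a ``{vital}_src`` provenance column per vital
    (``first``/``second``/``derived``/``missing``).
    """
    filtered, _ = filter_frame(cases, ranges)
    out = pd.DataFrame(
        {
            "case_id": filtered["case_id"].to_numpy(),
            "age": filtered.get("age", pd.Series(np.nan, index=filtered.index)).to_numpy(),
            "staff": filtered.get("staff", pd.Series("", index=filtered.index)).to_numpy(),
        }
    )
    for vital in VITALS:
        c1, c2 = filtered[f"{vital}_1"], filtered[f"{vital}_2"]
        has1, has2 = c1.notna().to_numpy(), c2.notna().to_numpy()
        if precedence == "first":
            take_second = ~has1 & has2
        else:
            take_second = np.zeros(len(filtered), dtype=bool)
            both = has1 & has2
            if both.any():
                idx = np.flatnonzero(both)
                take_second[idx] = [
                    _worse_is_second(vital, c1.iloc[i], c2.iloc[i]) for i in idx
                ]
            take_second |= ~has1 & has2
        value = c1.where(~take_second, c2)
        src = np.where(
            has1 | has2, np.where(take_second, "second", "first"), "missing"
        )
        out[vital] = value.to_numpy(dtype=object)
        out[f"{vital}_src"] = src
    # consciousness fallback from GCS
    con = out["consciousness"]
    fb = con.isna() & out["gcs"].notna()
    if fb.any():
        out.loc[fb, "consciousness"] = [
            gcs_to_acvpu(g) for g in quantize(out.loc[fb, "gcs"].to_numpy(dtype=float))
        ]
        out.loc[fb, "consciousness_src"] = "derived"
    # dtype normalisation
    for vital in NUMERIC_VITALS:
        out[vital] = pd.to_numeric(out[vital], errors="coerce")
    out["on_oxygen"] = out["on_oxygen"].astype("boolean")
    return out


@dataclass(frozen=True)
class MissingStrategy:
    """A named missing-data strategy plus its parameters."""

    name: str
    seed: int = 0
    age_bands: tuple = (18, 40, 65, 80)
    normal_values: dict = field(default_factory=lambda: dict(NORMAL_VALUES))
    worst_values: dict = field(default_factory=lambda: dict(WORST_VALUES))

    def __post_init__(self):
        name = STRATEGY_ALIASES.get(self.name)
        if name is None:
            raise ConfigurationError(
                f"name: unknown missing-data strategy {self.name!r}; "
                f"expected one of {sorted(set(STRATEGY_ALIASES))}"
            )
        object.__setattr__(self, "name", name)
        _validate_normal_table(self.normal_values)
        _validate_worst_table(self.worst_values)


def _validate_normal_table(table: dict) -> None:
    """The normal-value table must score 0 points in every tool."""
    from . import scores

    v = Vitals(**table)
    for tool in scores.TOOLS:
        s = scores.compute_score(tool, v)
        if s != 0:
            raise ConfigurationError(
                f"normal_values: scores {s} (not 0) in {tool}"
            )


def _validate_worst_table(table: dict) -> None:
    """The worst-value table must attain each tool's maximal score."""
    from . import scores
    from .tables import default_tables

    v = Vitals(**table)
    for tool, tab in default_tables().items():
        s = scores.compute_score(tool, v)
        if s != tab.max_score:
            raise ConfigurationError(
                f"worst_values: scores {s} (not max {tab.max_score}) in {tool}"
            )


def apply_missing_strategy(
    resolved: pd.DataFrame, strategy: MissingStrategy
) -> pd.DataFrame:
    """Fill (or flag) remaining missing vitals according to the strategy.

    Adds an ``excluded`` column (only ever True under complete_case) and
    updates the provenance columns of imputed entries to
    ``imputed-<strategy>``. After any strategy except complete_case no
    tool-required vital is missing.
    """
    out = resolved.copy()
    missing = {vital: out[vital].isna().to_numpy() for vital in VITALS}
    mentation_missing = missing["gcs"] & missing["consciousness"]

    if strategy.name == "complete_case":
        excluded = mentation_missing.copy()
        for vital in REQUIRED_VITALS:
            excluded |= missing[vital]
        out["excluded"] = excluded
        n_exc = int(excluded.sum())
        if n_exc:
            logger.info("complete_case: excluded %d of %d records", n_exc, len(out))
        return out

    out["excluded"] = False
    tag = f"imputed-{strategy.name}"
    if strategy.name in ("missing_as_normal", "missing_as_worst"):
        table = (
            strategy.normal_values
            if strategy.name == "missing_as_normal"
            else strategy.worst_values
        )
        for vital in VITALS:
            mask = missing[vital]
            if mask.any():
                out.loc[mask, vital] = table[vital]
                out.loc[mask, f"{vital}_src"] = tag
        return out

    # hotdeck: seeded draws from documented donors within age-band x staff
    # strata; the strata are blind to the outcome label by construction.
    rng = np.random.default_rng(strategy.seed)
    ages = pd.to_numeric(out["age"], errors="coerce").to_numpy(dtype=float)
    band = np.digitize(np.nan_to_num(ages, nan=-1.0), strategy.age_bands)
    staff = out["staff"].astype(str).to_numpy()
    strata = pd.Series([f"{b}|{s}" for b, s in zip(band, staff)])
    for vital in VITALS:
        mask = missing[vital]
        if not mask.any():
            continue
        donors_all = out.loc[~mask, vital].to_numpy()
        filled = out[vital].copy()
        for stratum in sorted(strata[mask].unique()):
            rows = mask & (strata == stratum).to_numpy()
            donors = out.loc[(~mask) & (strata == stratum).to_numpy(), vital].to_numpy()
            if len(donors) == 0:
                logger.warning(
                    "hotdeck: empty donor stratum %r for %s; using global pool",
                    stratum,
                    vital,
                )
                donors = donors_all
            if len(donors) == 0:
                logger.warning(
                    "hotdeck: no donors at all for %s; using normal value", vital
                )
                donors = np.array([strategy.normal_values[vital]], dtype=object)
            filled.loc[rows] = rng.choice(donors, size=int(rows.sum()), replace=True)
        out[vital] = filled
        out.loc[mask, f"{vital}_src"] = tag
    for vital in NUMERIC_VITALS:
        out[vital] = pd.to_numeric(out[vital], errors="coerce")
    out["on_oxygen"] = out["on_oxygen"].astype("boolean")
    return out


def preprocess_cases(
    cases: pd.DataFrame,
    strategy: MissingStrategy | str,
    ranges: PlausibilityRanges = DEFAULT_RANGES,
    precedence: Literal["first", "worst"] = "first",
    seed: int = 0,
) -> pd.DataFrame:
    """Full preprocessing pipeline: filter -> resolve -> strategy."""
    if isinstance(strategy, str):
        strategy = MissingStrategy(name=strategy, seed=seed)
    resolved = resolve_frame(cases, ranges=ranges, precedence=precedence)
    return apply_missing_strategy(resolved, strategy)
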