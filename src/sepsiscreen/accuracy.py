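"""Diagnostic-accuracy statistics and the hypothesis tests used in reports.

For a dichotomous screening rule the AUROC is the two-segment trapezoid,
(sensitivity + specificity) / 2. Binomial confidence intervals default to the
Wilson score method (a Wald variant is available behind a flag). McNemar's
chi-square is computed without continuity correction by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._round import round_half_up

__all__ = [
    "ConfusionMatrix",
    "Proportion",
    "AccuracySummary",
    "confusion",
    "accuracy_summary",
    "wilson_ci",
    "wald_ci",
    "mcnemar",
    "mcnemar_counts",
    "chi2_cramers_v",
    "bonferroni",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Proportion:
    """A proportion with its binomial confidence interval."""

    value: float
    lower: float
    upper: float
    successes: int
    trials: int

    def pct(self, ndigits: int = 1) -> float:
        return round_half_up(100.0 * self.value, ndigits)


@dataclass(frozen=True)
class AccuracySummary:
    cm: ConfusionMatrix
    sensitivity: Proportion
    specificity: Proportion
    ppv: Optional[Proportion]      # None (flagged) when tp + fp == 0
    npv: Optional[Proportion]
    lr_plus: float                 # inf when specificity == 1
    lr_minus: float
    auroc: float
    positivity_rate: Proportion


def confusion(flags: Sequence, labels: Sequence) -> ConfusionMatrix:
    """Exact 2x2 cross-tabulation of screening flags against labels."""
    flags = np.asarray(flags)
    labels = np.asarray(labels)
    if flags.shape != labels.shape or flags.ndim != 1:
        raise ValueError(
            f"length mismatch: {flags.shape} flags vs {labels.shape} labels"
        )
    if flags.dtype == object or labels.dtype == object:
        if any(f is None for f in flags) or any(l is None for l in labels):
            raise ValueError("flags/labels must not contain missing entries")
    f = flags.astype(bool)
    l = labels.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(f & l)),
        fp=int(np.sum(f & ~l)),
        fn=int(np.sum(~f & l)),
        tn=int(np.sum(~f & ~l)),
    )


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    n = float(trials)
    p = successes / n
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = (p + z2 / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def wald_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Plain Wald interval, clipped to [0, 1]; offered for comparison only."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    p = successes / trials
    half = z * math.sqrt(p * (1.0 - p) / trials)
    return (max(0.0, p - half), min(1.0, p + half))


def proportion(successes: int, trials: int, level: float = 0.95, method: str = "wilson") -> Proportion:
    ci = {"wilson": wilson_ci, "wald": wald_ci}[method](successes, trials, level)
    return Proportion(successes / trials, ci[0], ci[1], int(successes), int(trials))


def accuracy_summary(
    cm: ConfusionMatrix, level: float = 0.95, ci_method: str = "wilson"
) -> AccuracySummary:
    """All Table-2-style statistics derived from one confusion matrix."""
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    se = proportion(cm.tp, cm.n_pos, level, ci_method)
    sp = proportion(cm.tn, cm.n_neg, level, ci_method)
    ppv = proportion(cm.tp, cm.tp + cm.fp, level, ci_method) if cm.tp + cm.fp > 0 else None
    npv = proportion(cm.tn, cm.tn + cm.fn, level, ci_method) if cm.tn + cm.fn > 0 else None
    lr_plus = se.value / (1.0 - sp.value) if sp.value < 1.0 else math.inf
    lr_minus = (1.0 - se.value) / sp.value if sp.value > 0.0 else math.inf
    auroc = (se.value + sp.value) / 2.0
    pos = proportion(cm.tp + cm.fp, cm.n, level, ci_method)
    return AccuracySummary(
        cm=cm,
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        lr_plus=lr_plus,
        lr_minus=lr_minus,
        auroc=auroc,
        positivity_rate=pos,
    )


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    pvalue: float
    b: int            # first positive, second negative
    c: int            # first negative, second positive
    degenerate: bool  # no discordant pairs


def mcnemar_counts(b: int, c: int, correction: bool = False) -> McNemarResult:
    """McNemar's chi-square from the two discordant counts."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return McNemarResult(0.0, 1.0, 0, 0, True)
    diff = abs(b - c) - (1.0 if correction else 0.0)
    diff = max(diff, 0.0)
    statistic = diff * diff / (b + c)
    pvalue = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic, pvalue, int(b), int(c), False)


def mcnemar(flags_a: Sequence, flags_b: Sequence, correction: bool = False) -> McNemarResult:
    """Paired comparison of two screening rules on the same cases."""
    a = np.asarray(flags_a)
    bf = np.asarray(flags_b)
    if a.shape != bf.shape or a.ndim != 1:
        raise ValueError("paired flag vectors must have equal length")
    a = a.astype(bool)
    bf = bf.astype(bool)
    return mcnemar_counts(int(np.sum(a & ~bf)), int(np.sum(~a & bf)), correction)


def chi2_cramers_v(table) -> tuple[float, float, float]:
    """Pearson chi-square (no continuity correction) plus Cramer's V."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a contingency table of at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    n = t.sum()
    v = math.sqrt(chi2 / (n * (min(t.shape) - 1)))
    return float(chi2), float(p), float(v)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Reject H0_i iff p_i <= alpha / m (m = number of tests)."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    if m == 0:
        return []
    return [p <= alpha / m for p in ps]
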