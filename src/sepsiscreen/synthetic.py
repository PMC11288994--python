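"""Synthetic EMS cohort generator.

Produces case/outcome tables with the statistical structure the downstream
analysis assumes: configurable condition prevalences, vital-sign
distributions shifted in septic cases, per-variable documentation rates by
staff type, optional implausible-value contamination and mortality follow-up.
The generator's contract is distributional recovery (prevalences, completeness
rates, mean shifts, case-fatality rates), not clinical realism; every
distributional assumption is a config field.
"""

from __future__ import annotations

from typing import Dict, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import stats

from ._round import quantize
from .errors import ConfigurationError
from .vitals import DOCUMENTED_VARIABLES, PLAUSIBILITY_RANGES, gcs_to_acvpu

#: Per-variable documentation rates (share of cases with at least one filled
#: assessment slot), by staff type: EP = prehospital emergency physicians,
#: PM = paramedics.
DEFAULT_DOC_RATES: Dict[str, Dict[str, float]] = {
    "EP": {
        "temp": 0.198,
        "rr": 0.533,
        "gcs": 0.678,
        "spo2": 0.854,
        "sbp": 0.869,
        "hr": 0.887,
        "consciousness": 0.686,
    },
    "PM": {
        "temp": 0.177,
        "rr": 0.270,
        "gcs": 0.781,
        "spo2": 0.790,
        "sbp": 0.788,
        "hr": 0.815,
        "consciousness": 0.869,
    },
}

#: Truncated-normal parameters (mean, sd) of the non-septic vital
#: distributions; assumptions, not reproductions of any published values.
DEFAULT_VITAL_MEANS: Dict[str, Tuple[float, float]] = {
    "rr": (16.0, 4.0),
    "spo2": (97.0, 2.0),
    "sbp": (125.0, 20.0),
    "hr": (80.0, 15.0),
    "temp": (36.8, 0.6),
    "gcs": (14.5, 1.5),
}

#: Additive mean shifts applied to septic cases.
DEFAULT_SEVERITY_SHIFT: Dict[str, float] = {
    "rr": 8.0,
    "spo2": -4.0,
    "sbp": -20.0,
    "hr": 20.0,
    "temp": 1.2,
    "gcs": -2.0,
}

#: (in-hospital, 30-day) death probabilities per condition. The sepsis rates
#: are the study's; the others are plausible defaults on the same scale.
DEFAULT_FATALITY: Dict[str, Tuple[float, float]] = {
    "sepsis": (0.316, 0.317),
    "mi": (0.10, 0.134),
    "stroke": (0.09, 0.118),
    "none": (0.01, 0.015),
}

#: Out-of-range draw windows for implausible-value contamination, strictly
#: outside the plausibility ranges after vital-specific quantization.
IMPLAUSIBLE_WINDOWS: Dict[str, Tuple[Optional[Tuple[float, float]], Tuple[float, float]]] = {
    "temp": ((5.0, 20.0), (46.0, 60.0)),
    "rr": (None, (81.0, 250.0)),
    "hr": ((0.0, 8.4), (281.0, 500.0)),
    "sbp": ((0.0, 38.4), (321.0, 600.0)),
    "spo2": ((1.0, 38.4), (101.0, 130.0)),
    "gcs": ((0.0, 1.4), (16.0, 25.0)),
}


class CohortConfig(BaseModel):
    """Everything the generator needs; all fractions live in [0, 1]."""

    model_config = ConfigDict(extra="forbid")

    n_cases: int = Field(ge=0, default=4503)
    sepsis_prevalence: float = Field(ge=0.0, le=1.0, default=78 / 4503)
    mi_prevalence: float = Field(ge=0.0, le=1.0, default=0.026)
    stroke_prevalence: float = Field(ge=0.0, le=1.0, default=0.027)
    exact_counts: bool = False
    ep_fraction: float = Field(ge=0.0, le=1.0, default=3483 / 110419)
    doc_rates: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DOC_RATES.items()}
    )
    missing_mode: Literal["mcar", "mar"] = "mcar"
    missing_corr: float = Field(ge=0.0, lt=1.0, default=0.0)
    mar_shift: float = 0.5
    slot_probs: Tuple[float, float, float] = (0.6, 0.1, 0.3)
    implausible_rate: float = Field(ge=0.0, le=1.0, default=0.0)
    vital_means: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_VITAL_MEANS)
    )
    severity_shift: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_SHIFT)
    )
    on_oxygen_rate: float = Field(ge=0.0, le=1.0, default=0.15)
    on_oxygen_rate_septic: float = Field(ge=0.0, le=1.0, default=0.40)
    suspicion_rates: Dict[str, float] = Field(
        default_factory=lambda: {"PM": 0.0, "EP": 5 / 3483}
    )
    fatality: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_FATALITY)
    )
    transport_rate: float = Field(ge=0.0, le=1.0, default=0.85)
    p_male: float = Field(ge=0.0, le=1.0, default=0.5)
    age_mean: float = 62.0
    age_sd: float = Field(gt=0.0, default=21.0)
    age_range: Tuple[float, float] = (18.0, 105.0)
    follow_up_days: int = Field(ge=1, default=30)
    seed: int = 0

    @field_validator("doc_rates")
    @classmethod
    def _check_doc_rates(cls, v):
        for staff, rates in v.items():
            if staff not in ("PM", "EP"):
                raise ValueError(f"doc_rates: unknown staff type {staff!r}")
            missing = set(DOCUMENTED_VARIABLES) - set(rates)
            if missing:
                raise ValueError(f"doc_rates[{staff}]: missing variables {sorted(missing)}")
            for var, rate in rates.items():
                if var not in DOCUMENTED_VARIABLES:
                    raise ValueError(f"doc_rates[{staff}]: unknown variable {var!r}")
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"doc_rates[{staff}][{var}]: rate must be in [0, 1]")
        if set(v) != {"PM", "EP"}:
            raise ValueError("doc_rates: must define both PM and EP staff types")
        return v

    @field_validator("suspicion_rates")
    @classmethod
    def _check_suspicion(cls, v):
        for staff, rate in v.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"suspicion_rates[{staff}]: rate must be in [0, 1]")
        return v

    @field_validator("fatality")
    @classmethod
    def _check_fatality(cls, v):
        for cond, (hosp, d30) in v.items():
            if not (0.0 <= hosp <= 1.0 and 0.0 <= d30 <= 1.0):
                raise ValueError(f"fatality[{cond}]: probabilities must be in [0, 1]")
            if hosp > d30:
                raise ValueError(
                    f"fatality[{cond}]: hospital fatality cannot exceed 30-day fatality"
                )
        return v

    @model_validator(mode="after")
    def _check_slots(self):
        if any(p < 0 for p in self.slot_probs) or abs(sum(self.slot_probs) - 1.0) > 1e-9:
            raise ValueError("slot_probs: must be non-negative and sum to 1")
        return self


def _load_config(obj) -> CohortConfig:
    if isinstance(obj, CohortConfig):
        return obj
    try:
        return CohortConfig.model_validate(obj)
    except Exception as exc:  # pydantic ValidationError carries field names
        raise ConfigurationError(str(exc)) from exc


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _bernoulli(rng, p, n, exact=False):
    if exact:
        k = int(round(p * n))
        out = np.zeros(n, dtype=bool)
        out[rng.permutation(n)[:k]] = True
        return out
    return rng.random(n) < p


def generate_cohort(config) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate fully documented case and outcome tables.

    Returns ``(cases, outcomes)``. Cases carry both assessment slots filled;
    apply :func:`inject_missingness` / :func:`inject_implausible` afterwards
    to emulate documentation deficiencies. Identical config (incl. seed)
    yields identical tables.
    """
    cfg = _load_config(config)
    n = cfg.n_cases
    rng = np.random.default_rng(cfg.seed)

    case_id = np.array([f"c{i:07d}" for i in range(n)])
    age = np.round(
        _truncnorm(rng, cfg.age_mean, cfg.age_sd, cfg.age_range[0], cfg.age_range[1], n)
    ).astype(int) if n else np.array([], dtype=int)
    sex = np.where(rng.random(n) < cfg.p_male, "m", "f")
    staff = np.where(rng.random(n) < cfg.ep_fraction, "EP", "PM")

    sepsis = _bernoulli(rng, cfg.sepsis_prevalence, n, cfg.exact_counts)
    mi = _bernoulli(rng, cfg.mi_prevalence, n, cfg.exact_counts)
    stroke = _bernoulli(rng, cfg.stroke_prevalence, n, cfg.exact_counts)

    # true vitals, shifted in septic cases, truncated to plausibility ranges
    vitals1: dict[str, np.ndarray] = {}
    for vital in ("rr", "spo2", "sbp", "hr", "temp", "gcs"):
        mean, sd = cfg.vital_means[vital]
        shift = cfg.severity_shift.get(vital, 0.0)
        lo, hi = PLAUSIBILITY_RANGES[vital]
        means = mean + shift * sepsis
        # per-case means: single vectorised inverse-CDF truncated-normal draw
        u = rng.random(n)
        a = stats.norm.cdf((lo - means) / sd)
        b = stats.norm.cdf((hi - means) / sd)
        base = means + sd * stats.norm.ppf(a + u * (b - a))
        decimals = 1 if vital == "temp" else 0
        vitals1[vital] = np.clip(quantize(base, decimals), lo, hi)
    vitals1["gcs"] = vitals1["gcs"].astype(int).astype(float)
    on_ox = rng.random(n) < np.where(sepsis, cfg.on_oxygen_rate_septic, cfg.on_oxygen_rate)
    consciousness1 = np.array([gcs_to_acvpu(g) for g in vitals1["gcs"]], dtype=object)

    # second assessment: first slot plus small measurement drift
    vitals2: dict[str, np.ndarray] = {}
    for vital in ("rr", "spo2", "sbp", "hr", "temp"):
        _, sd = cfg.vital_means[vital]
        lo, hi = PLAUSIBILITY_RANGES[vital]
        decimals = 1 if vital == "temp" else 0
        drift = rng.normal(0.0, 0.15 * sd, n)
        vitals2[vital] = np.clip(quantize(vitals1[vital] + drift, decimals), lo, hi)
    vitals2["gcs"] = vitals1["gcs"].copy()
    consciousness2 = consciousness1.copy()

    suspicion = np.zeros(n, dtype=bool)
    for st, rate in cfg.suspicion_rates.items():
        mask = staff == st
        suspicion[mask] = rng.random(int(mask.sum())) < rate
    transported = rng.random(n) < cfg.transport_rate

    cases = pd.DataFrame(
        {
            "case_id": case_id,
            "age": age,
            "sex": sex,
            "staff": staff,
            "transported": transported,
            "suspicion_documented": suspicion,
        }
    )
    for slot, vit, con in ((1, vitals1, consciousness1), (2, vitals2, consciousness2)):
        for vital in ("rr", "spo2", "sbp", "hr", "temp", "gcs"):
            cases[f"{vital}_{slot}"] = vit[vital]
        cases[f"on_oxygen_{slot}"] = pd.array(on_ox, dtype="boolean")
        cases[f"consciousness_{slot}"] = con

    outcomes = _generate_outcomes(rng, cfg, case_id, sepsis, mi, stroke)
    return cases, outcomes


def _generate_outcomes(rng, cfg, case_id, sepsis, mi, stroke) -> pd.DataFrame:
    n = len(case_id)
    p_hosp = np.full(n, cfg.fatality["none"][0])
    p_30 = np.full(n, cfg.fatality["none"][1])
    # a case with several conditions takes the highest applicable risk
    for cond, flags in (("stroke", stroke), ("mi", mi), ("sepsis", sepsis)):
        hosp, d30 = cfg.fatality[cond]
        p_hosp = np.where(flags & (p_30 < d30), hosp, p_hosp)
        p_30 = np.where(flags & (p_30 < d30), d30, p_30)
    u = rng.random(n)
    died_hosp = u < p_hosp
    died_30 = u < p_30
    death_day = np.full(n, np.nan)
    if n:
        death_day[died_30] = rng.integers(0, cfg.follow_up_days + 1, int(died_30.sum()))
    return pd.DataFrame(
        {
            "case_id": case_id,
            "sepsis": sepsis,
            "mi": mi,
            "stroke": stroke,
            "died_in_hospital": died_hosp,
            "death_day": death_day,
        }
    )


def inject_missingness(
    cases: pd.DataFrame,
    doc_rates: Dict[str, Dict[str, float]] | None = None,
    seed: int = 0,
    mode: Literal["mcar", "mar"] = "mcar",
    corr: float = 0.0,
    mar_shift: float = 0.5,
    severity: Optional[np.ndarray] = None,
    slot_probs: Tuple[float, float, float] = (0.6, 0.1, 0.3),
) -> pd.DataFrame:
    """Blank assessment slots so per-variable completeness matches doc_rates.

    A variable counts as documented when at least one slot survives; the
    documented/undocumented indicator is drawn from a Gaussian copula with
    exchangeable correlation ``corr`` across variables (``corr=0`` is MCAR).
    Under ``mode="mar"`` the documentation propensity of severe cases
    (boolean ``severity`` array) is shifted down by ``mar_shift`` latent SDs.
    The supplemental-oxygen flag follows the saturation reading's slots.
    """
    doc_rates = doc_rates if doc_rates is not None else DEFAULT_DOC_RATES
    for staff, rates in doc_rates.items():
        for var, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"doc_rates[{staff}][{var}]: rate must be in [0, 1]")
        missing = set(DOCUMENTED_VARIABLES) - set(rates)
        if missing:
            raise ConfigurationError(f"doc_rates[{staff}]: missing variables {sorted(missing)}")
    if mode == "mar" and severity is None:
        raise ConfigurationError("severity: required when mode='mar'")

    out = cases.copy()
    n = len(out)
    rng = np.random.default_rng(seed)
    staff_col = out["staff"].astype(str).to_numpy()
    sev = np.asarray(severity, dtype=bool) if severity is not None else np.zeros(n, bool)

    sq_corr, sq_ind = np.sqrt(corr), np.sqrt(1.0 - corr)
    common = rng.standard_normal(n)
    for var in DOCUMENTED_VARIABLES:
        z = sq_corr * common + sq_ind * rng.standard_normal(n)
        if mode == "mar":
            z = z + mar_shift * sev
        documented = np.zeros(n, dtype=bool)
        for staff in sorted(doc_rates):
            mask = staff_col == staff
            thresh = stats.norm.ppf(doc_rates[staff][var])
            documented[mask] = z[mask] <= thresh
        # among documented: which slots carry the value
        pattern = rng.choice(3, size=n, p=list(slot_probs))  # 0=first,1=second,2=both
        blank1 = ~documented | (documented & (pattern == 1))
        blank2 = ~documented | (documented & (pattern == 0))
        _blank(out, f"{var}_1", blank1)
        _blank(out, f"{var}_2", blank2)
        if var == "spo2":
            _blank(out, "on_oxygen_1", blank1)
            _blank(out, "on_oxygen_2", blank2)
    return out


def _blank(df: pd.DataFrame, col: str, mask: np.ndarray) -> None:
    if not mask.any():
        return
    if df[col].dtype == object or str(df[col].dtype) == "boolean":
        if df[col].dtype == object:
            df.loc[mask, col] = None
        else:
            df.loc[mask, col] = pd.NA
    else:
        if df[col].dtype != float:
            df[col] = df[col].astype(float)
        df.loc[mask, col] = np.nan


def inject_implausible(
    cases: pd.DataFrame, rate: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace a fraction of documented numeric values by implausible ones.

    Each documented numeric entry is independently replaced with probability
    ``rate`` by a draw strictly outside its plausibility range (low or high
    side, 50/50 where both exist). Returns the contaminated table plus a log
    of every replacement (case_id, variable, slot, original, injected).
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("implausible_rate: must be in [0, 1]")
    out = cases.copy()
    log_rows = []
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        return out, pd.DataFrame(
            columns=["case_id", "variable", "slot", "original", "injected"]
        )
    for var, (low_win, high_win) in IMPLAUSIBLE_WINDOWS.items():
        decimals = 1 if var == "temp" else 0
        for slot in (1, 2):
            col = f"{var}_{slot}"
            if col not in out.columns:
                continue
            vals = out[col].to_numpy(dtype=float)
            documented = ~np.isnan(vals)
            hit = documented & (rng.random(len(out)) < rate)
            if not hit.any():
                continue
            k = int(hit.sum())
            use_high = rng.random(k) < 0.5 if low_win is not None else np.ones(k, bool)
            draws = np.empty(k)
            for side, win in ((False, low_win), (True, high_win)):
                sel = use_high == side
                if win is None or not sel.any():
                    continue
                draws[sel] = rng.uniform(win[0], win[1], int(sel.sum()))
            injected = quantize(draws, decimals)
            idx = np.flatnonzero(hit)
            originals = vals[idx]
            out[col] = out[col].astype(float)
            out.loc[out.index[idx], col] = injected
            log_rows.extend(
                {
                    "case_id": out["case_id"].iloc[i],
                    "variable": var,
                    "slot": slot,
                    "original": o,
                    "injected": j,
                }
                for i, o, j in zip(idx, originals, injected)
            )
    log = pd.DataFrame(log_rows, columns=["case_id", "variable", "slot", "original", "injected"])
    return out, log


def simulate_study(config) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and apply documentation gaps plus contamination.

    Returns ``(cases, outcomes, implausible_log)``. Seeds for the three
    stages derive deterministically from ``config.seed``.
    """
    cfg = _load_config(config)
    cases, outcomes = generate_cohort(cfg)
    sev = outcomes["sepsis"].to_numpy(dtype=bool)
    cases = inject_missingness(
        cases,
        cfg.doc_rates,
        seed=cfg.seed + 1,
        mode=cfg.missing_mode,
        corr=cfg.missing_corr,
        mar_shift=cfg.mar_shift,
        severity=sev if cfg.missing_mode == "mar" else None,
        slot_probs=cfg.slot_probs,
    )
    cases, log = inject_implausible(cases, cfg.implausible_rate, seed=cfg.seed + 2)
    return cases, outcomes, log
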