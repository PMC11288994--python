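"""Core vital-sign value objects, plausibility ranges, and reference tables.

One prehospital contact carries up to two assessment slots per vital sign.
The eight analysis vitals are: respiratory rate (``rr``), oxygen saturation
(``spo2``), supplemental oxygen flag (``on_oxygen``), systolic blood pressure
(``sbp``), heart rate (``hr``), body temperature (``temp``), Glasgow Coma
Scale (``gcs``) and the ACVPU consciousness category (``consciousness``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

VITALS = ("rr", "spo2", "on_oxygen", "sbp", "hr", "temp", "gcs", "consciousness")

#: Vitals with a numeric plausibility range (everything except the oxygen
#: flag and the consciousness category).
NUMERIC_VITALS = ("rr", "spo2", "sbp", "hr", "temp", "gcs")

#: The seven separately documented variables tracked in completeness
#: analyses (the oxygen flag rides along with the saturation reading).
DOCUMENTED_VARIABLES = ("temp", "rr", "gcs", "spo2", "sbp", "hr", "consciousness")

ACVPU = ("A", "C", "V", "P", "U")

#: Closed intervals of medically acceptable values; anything outside is
#: treated as a documentation artefact and removed before analysis.
PLAUSIBILITY_RANGES: dict[str, tuple[float, float]] = {
    "temp": (25.0, 45.0),
    "rr": (1.0, 80.0),
    "hr": (10.0, 280.0),
    "sbp": (40.0, 320.0),
    "spo2": (40.0, 100.0),
    "gcs": (3.0, 15.0),
}

#: Substitution table for the missing-as-normal strategy. Every entry scores
#: zero points in all four screening tools (verified when a strategy is
#: constructed).
NORMAL_VALUES: dict[str, object] = {
    "rr": 14.0,  # must score 0 everywhere; 15-20 already scores 1 in MEWS
    "spo2": 98.0,
    "on_oxygen": False,
    "sbp": 120.0,
    "hr": 75.0,
    "temp": 37.0,
    "gcs": 15.0,
    "consciousness": "A",
}

#: Substitution table for the missing-as-worst strategy. Every entry attains
#: the maximal number of points in each tool that uses it.
WORST_VALUES: dict[str, object] = {
    "rr": 40.0,
    "spo2": 50.0,
    "on_oxygen": True,
    "sbp": 50.0,
    "hr": 140.0,
    "temp": 30.0,
    "gcs": 3.0,
    "consciousness": "U",
}


@dataclass(frozen=True)
class Vitals:
    """One set of vital-sign values; ``None`` marks a missing entry."""

    rr: Optional[float] = None
    spo2: Optional[float] = None
    on_oxygen: Optional[bool] = None
    sbp: Optional[float] = None
    hr: Optional[float] = None
    temp: Optional[float] = None
    gcs: Optional[float] = None
    consciousness: Optional[str] = None

    def replace(self, **kwargs) -> "Vitals":
        return replace(self, **kwargs)

    def get(self, vital: str):
        return getattr(self, vital)


def gcs_to_acvpu(gcs: float) -> str:
    """Map a Glasgow Coma Scale value onto the ACVPU consciousness scale.

    Default convention: 15 -> A, 13-14 -> V, 9-12 -> P, <=8 -> U. "C" (new
    confusion) is never auto-derived; it can only come from documented data.
    This mapping is a convention, not a validated crosswalk, and is
    overridable wherever it is used.
    """
    if gcs >= 15:
        return "A"
    if gcs >= 13:
        return "V"
    if gcs >= 9:
        return "P"
    return "U"
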