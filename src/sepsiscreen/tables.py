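"""Loading and validation of the versioned screening-score tables.

Tables live in a JSON data file, not in code, so they can be reviewed and
swapped without touching the calculators. An interval component is stored as
ascending breaks ``b_1..b_k`` plus ``k+1`` point values; after half-up
quantization (one decimal for temperature, integers elsewhere) a value ``v``
scores ``points[i]`` with ``i`` the number of breaks ``<= v``. This makes
coverage and disjointness of the bands structural; validation checks the
remaining invariants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np

from ._round import quantize
from .vitals import ACVPU

#: Decimal places used to quantize a measurement before band lookup.
QUANTIZE_DECIMALS = {"temp": 1, "rr": 0, "hr": 0, "sbp": 0, "spo2": 0, "gcs": 0}

TOOLS = ("qsofa", "sirs", "mews", "news2")


@dataclass(frozen=True)
class Component:
    vital: str
    kind: str                       # "interval" or "category"
    breaks: tuple = ()              # interval components only
    points: tuple = ()              # interval: len(breaks) + 1 entries
    category_points: Mapping[str, int] | None = None
    decimals: int = 0

    @property
    def max_points(self) -> int:
        if self.kind == "category":
            return max(self.category_points.values())
        return max(self.points)

    def lookup(self, value) -> int:
        """Points for a single value (already non-missing)."""
        if self.kind == "category":
            key = _category_key(value)
            return self.category_points[key]
        q = quantize([value], self.decimals)[0]
        idx = int(np.searchsorted(self.breaks, q, side="right"))
        return self.points[idx]

    def lookup_array(self, values) -> np.ndarray:
        if self.kind == "category":
            keys = [_category_key(v) for v in values]
            return np.array([self.category_points[k] for k in keys], dtype=int)
        q = quantize(values, self.decimals)
        idx = np.searchsorted(self.breaks, q, side="right")
        return np.asarray(self.points, dtype=int)[idx]


def _category_key(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    return str(value)


@dataclass(frozen=True)
class ScoreTable:
    tool: str
    name: str
    threshold: int
    max_score: int
    components: Mapping[str, Component]


def _build_component(vital: str, raw: dict) -> Component:
    kind = raw["kind"]
    if kind == "category":
        pts = {str(k): int(v) for k, v in raw["points"].items()}
        if any(p < 0 for p in pts.values()):
            raise ValueError(f"{vital}: negative points")
        if vital == "consciousness" and set(pts) != set(ACVPU):
            raise ValueError(f"{vital}: categories must be exactly {ACVPU}")
        return Component(vital=vital, kind="category", category_points=pts)
    breaks = tuple(float(b) for b in raw["breaks"])
    points = tuple(int(p) for p in raw["points"])
    if list(breaks) != sorted(set(breaks)):
        raise ValueError(f"{vital}: breaks must be strictly increasing")
    if len(points) != len(breaks) + 1:
        raise ValueError(f"{vital}: need len(breaks)+1 point entries")
    if any(p < 0 for p in points):
        raise ValueError(f"{vital}: negative points")
    return Component(
        vital=vital,
        kind="interval",
        breaks=breaks,
        points=points,
        decimals=QUANTIZE_DECIMALS[vital],
    )


def _build_table(tool: str, raw: dict) -> ScoreTable:
    components = {
        vital: _build_component(vital, spec) for vital, spec in raw["components"].items()
    }
    threshold = int(raw["threshold"])
    max_score = int(raw["max_score"])
    if threshold < 1:
        raise ValueError(f"{tool}: threshold must be >= 1")
    attainable = sum(c.max_points for c in components.values())
    if attainable != max_score:
        raise ValueError(
            f"{tool}: declared max_score {max_score} != attainable {attainable}"
        )
    if threshold > max_score:
        raise ValueError(f"{tool}: threshold above max_score")
    return ScoreTable(
        tool=tool,
        name=raw.get("name", tool),
        threshold=threshold,
        max_score=max_score,
        components=components,
    )


def load_tables(path=None) -> dict[str, ScoreTable]:
    """Load and validate score tables from JSON (default: bundled file)."""
    if path is None:
        text = resources.files("sepsiscreen.data").joinpath("score_tables.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    tables = {tool: _build_table(tool, spec) for tool, spec in raw["tools"].items()}
    missing = set(TOOLS) - set(tables)
    if missing:
        raise ValueError(f"score-table file lacks tools: {sorted(missing)}")
    return tables


@lru_cache(maxsize=1)
def default_tables() -> dict[str, ScoreTable]:
    return load_tables()
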