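"""Half-up rounding helpers.

Report values are rounded half-up at display precision (37.05 -> 37.1), and
score-table lookups quantize measurements the same way before interval
comparison so that float representation noise (38.05 stored as 38.049999...)
cannot flip a band assignment.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding of a scalar (round() rounds half-to-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def quantize(values, decimals: int = 0) -> np.ndarray:
    """Vectorised half-up rounding, tolerant of binary representation error.

    A relative epsilon nudges values sitting a few ulp below .5 (the decimal
    literal they came from) over the boundary; genuine sub-.5 values are
    orders of magnitude further away and are unaffected.
    """
    arr = np.asarray(values, dtype=float)
    scale = 10.0 ** decimals
    scaled = arr * scale
    eps = 1e-9 * np.maximum(1.0, np.abs(scaled))
    out = np.floor(scaled + 0.5 + eps) / scale
    return out
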