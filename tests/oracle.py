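"""Independent brute-force score oracles for dual-route testing.

Hand-written if-chains per clinical band, deliberately not sharing any code
with the package's interval-lookup implementation. Temperatures are compared
in integer tenths to sidestep float boundaries; other vitals are half-up
rounded to integers.
"""

from decimal import ROUND_HALF_UP, Decimal


def _int_half_up(x) -> int:
    return int(Decimal(repr(float(x))).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def _tenths(x) -> int:
    return int(
        (Decimal(repr(float(x))) * 10).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    )


def oracle_qsofa(rr, sbp, gcs) -> int:
    pts = 0
    if _int_half_up(rr) >= 22:
        pts += 1
    if _int_half_up(sbp) <= 100:
        pts += 1
    if _int_half_up(gcs) < 15:
        pts += 1
    return pts


def oracle_sirs(temp, hr, rr) -> int:
    pts = 0
    t = _tenths(temp)
    if t < 360 or t > 380:
        pts += 1
    if _int_half_up(hr) > 90:
        pts += 1
    if _int_half_up(rr) > 20:
        pts += 1
    return pts


def oracle_mews(sbp, hr, rr, temp, avpu) -> int:
    s = _int_half_up(sbp)
    if s <= 70:
        pts = 3
    elif s <= 80:
        pts = 2
    elif s <= 100:
        pts = 1
    elif s <= 199:
        pts = 0
    else:
        pts = 2
    h = _int_half_up(hr)
    if h <= 40:
        pts += 2
    elif h <= 50:
        pts += 1
    elif h <= 100:
        pts += 0
    elif h <= 110:
        pts += 1
    elif h <= 129:
        pts += 2
    else:
        pts += 3
    r = _int_half_up(rr)
    if r <= 8:
        pts += 2
    elif r <= 14:
        pts += 0
    elif r <= 20:
        pts += 1
    elif r <= 29:
        pts += 2
    else:
        pts += 3
    t = _tenths(temp)
    if t < 350:
        pts += 2
    elif t <= 384:
        pts += 0
    else:
        pts += 2
    pts += {"A": 0, "C": 1, "V": 1, "P": 2, "U": 3}[avpu]
    return pts


def oracle_news2(rr, spo2, on_oxygen, sbp, hr, consciousness, temp) -> int:
    r = _int_half_up(rr)
    if r <= 8:
        pts = 3
    elif r <= 11:
        pts = 1
    elif r <= 20:
        pts = 0
    elif r <= 24:
        pts = 2
    else:
        pts = 3
    s = _int_half_up(spo2)
    if s <= 91:
        pts += 3
    elif s <= 93:
        pts += 2
    elif s <= 95:
        pts += 1
    if on_oxygen:
        pts += 2
    b = _int_half_up(sbp)
    if b <= 90:
        pts += 3
    elif b <= 100:
        pts += 2
    elif b <= 110:
        pts += 1
    elif b <= 219:
        pts += 0
    else:
        pts += 3
    h = _int_half_up(hr)
    if h <= 40:
        pts += 3
    elif h <= 50:
        pts += 1
    elif h <= 90:
        pts += 0
    elif h <= 110:
        pts += 1
    elif h <= 130:
        pts += 2
    else:
        pts += 3
    if consciousness != "A":
        pts += 3
    t = _tenths(temp)
    if t <= 350:
        pts += 3
    elif t <= 360:
        pts += 1
    elif t <= 380:
        pts += 0
    elif t <= 390:
        pts += 1
    else:
        pts += 2
    return pts
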