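"""Rounding and small-sample exact-test primitives shared across modules."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "pct_half_up"]


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero to ``digits`` decimals (table convention:
    69/190 prints as 36%, 18/80 as 23%)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct_half_up(x: int, n: int, digits: int = 0) -> float:
    """Percentage ``100*x/n`` rounded half-up; NaN when the denominator is 0
    (an undefined percentage is never reported as 0)."""
    if n == 0:
        return math.nan
    return round_half_up(100.0 * x / n, digits)
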