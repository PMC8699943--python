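"""Small shared helpers: half-up rounding and missing-value predicates."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Report tables print one-decimal percentages and likelihood ratios;
    banker's rounding (Python's built-in) would print 82.45 as 82.4 where
    the convention in clinical tables is 82.5.
    """
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def is_missing(value) -> bool:
    """True for None, NaN and pandas NA."""
    if value is None:
        return True
    try:
        return bool(value != value)  # NaN is not equal to itself
    except (TypeError, ValueError):
        return False
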