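"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

#: marker for undefined ratios (e.g. skew with zero denominator)
MISSING = math.nan


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as tabulated reports conventionally do.

    Python's builtin ``round`` is banker's rounding; composition and RSCU
    reports use half-up, which is what every checkable published table cell
    follows.
    """
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def is_missing(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
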