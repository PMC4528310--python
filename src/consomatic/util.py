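"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float | Fraction, ndigits: int = 1) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Printed percentages in clinical-genomics tables conventionally round
    5s up (26.75 -> 26.8), unlike banker's rounding.  Exact decimal/rational
    arithmetic avoids binary-float artifacts like 2.675 -> 2.67.
    """
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up, exact arithmetic."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator")
    return round_half_up(Fraction(100 * numerator, denominator), ndigits)
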