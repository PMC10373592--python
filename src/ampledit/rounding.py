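"""Exact rational percentage arithmetic with print-style rounding.

All user-facing percentages are computed as exact fractions and rounded
half-up at the last step, so results are reproducible across platforms.
"""

from __future__ import annotations

from fractions import Fraction
from numbers import Rational


def _to_fraction(x) -> Fraction:
    # Fraction(str(x)) treats floats as their decimal literal, which is what
    # a human reading printed values expects (0.1 means 1/10).
    if isinstance(x, float):
        return Fraction(str(x))
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(x)


def round_half_up(x, ndigits: int = 0):
    """Round to ``ndigits`` decimals with ties going away from zero-ward up.

    Returns an int when ``ndigits == 0``, else a float.
    """
    q = _to_fraction(x)
    scale = Fraction(10) ** ndigits
    scaled = q * scale
    floor = scaled.numerator // scaled.denominator
    if scaled - floor >= Fraction(1, 2):
        floor += 1
    if ndigits <= 0:
        return int(Fraction(floor, 1) / scale)
    return float(Fraction(floor, 1) / scale)


def percentage(numerator, denominator) -> Fraction:
    """Exact percentage ``100 * numerator / denominator``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    return 100 * _to_fraction(numerator) / _to_fraction(denominator)


def paper_pct(numerator, denominator):
    """Percentage at table precision: integer at >= 10 %, one decimal below."""
    p = percentage(numerator, denominator)
    if p >= 10:
        return round_half_up(p, 0)
    return round_half_up(p, 1)


def render_pct(value) -> str:
    """Render an already-rounded percentage the way the tables print it."""
    q = _to_fraction(value)
    if q >= 10:
        return str(round_half_up(q, 0))
    return f"{round_half_up(q, 1):.1f}"


def count_pct_cell(count: int, denominator: int) -> str:
    """``"N (P)"`` cell used by variant-frequency tables."""
    return f"{count} ({render_pct(percentage(count, denominator))})"
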