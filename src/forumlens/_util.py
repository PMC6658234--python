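"""Shared numeric formatting helpers.

Every percentage the package reports goes through one routine so that
summaries, CSV exports and tests agree to the digit.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_CENT = Decimal("0.01")


def round2(x: float) -> float:
    """Round to 2 decimal places, half away from zero ties going up."""
    return float(Decimal(repr(float(x))).quantize(_CENT, rounding=ROUND_HALF_UP))


def pct2(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator at 2 decimals, half-up, computed exactly.

    The division is done in decimal arithmetic so a count ratio such as
    181/1086 rounds from its true value (16.666...), not from a float.
    """
    if denominator == 0:
        raise ValueError("percentage undefined for a zero denominator")
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            _CENT, rounding=ROUND_HALF_UP
        )
    )
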