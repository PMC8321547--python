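"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals.

    Report percentages are rounded half-up (the convention of printed
    tables), not banker's rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(num: float, den: float, decimals: int = 2) -> float | None:
    """Percentage ``100*num/den`` rounded half-up; None when undefined."""
    if den == 0:
        return None
    return round_half_up(100.0 * num / den, decimals)
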