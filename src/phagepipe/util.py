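"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed percentages do.

    Python's builtin ``round`` is banker's rounding; reported percentages in
    this package follow the half-up convention (e.g. 76.45 -> 76.5).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded; 0.0 on empty input."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)
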