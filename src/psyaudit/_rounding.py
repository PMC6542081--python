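"""Half-up decimal rounding used throughout the report tables.

Python's built-in ``round`` is banker's rounding; audit tables are
conventionally printed with half-up rounding, so percentages such as
24/386 print as 6.2 and 69/386 as 17.9.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round *x* half-up to *ndigits* decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denom: int, ndigits: int = 1) -> float:
    """Percentage of *count* in *denom*, half-up to *ndigits* decimals.

    Raises ZeroDivisionError on a zero denominator; callers that need a
    guarded value must check the denominator themselves.
    """
    return round_half_up(100.0 * count / denom, ndigits)


def per_person(total: int, denom: int, ndigits: int = 2) -> float:
    """Average number of items per person, half-up rounded."""
    return round_half_up(total / denom, ndigits)
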