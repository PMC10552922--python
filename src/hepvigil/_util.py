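"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as clinical tables are printed.

    Python's built-in ``round`` uses banker's rounding; published frequency
    tables round 0.125 -> 0.13, so half-up is applied throughout.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage of ``count`` over ``denominator``, half-up rounded.

    A zero denominator yields 0.0 (empty tables are not an error).
    """
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, ndigits)
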