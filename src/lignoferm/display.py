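"""Report-time rounding and formatting helpers.

All computations keep full floating-point precision; rounding happens only
when a value is rendered for a table.  Half-up rounding is used so that,
e.g., 1.25 renders as 1.3 the way printed fermentation tables do, rather
than Python's default banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round *value* to *ndigits* decimals with ties going away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def fmt(value: float, ndigits: int = 1) -> str:
    """Render a number rounded half-up with a fixed number of decimals."""
    return f"{round_half_up(value, ndigits):.{ndigits}f}"
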