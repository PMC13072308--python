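"""Small shared helpers: half-up rounding and input validation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (``0.5 -> 1``), unlike banker's rounding.

    Titer-derived percentages are conventionally reported with half-up
    rounding (20/21 -> 95.2), which ``round()`` does not guarantee.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def require(condition: bool, message: str) -> None:
    """Raise ``ValueError`` with *message* unless *condition* holds."""
    if not condition:
        raise ValueError(message)
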