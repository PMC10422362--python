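"""Small shared numerics helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how percentages are usually printed.

    Python's builtin ``round`` is banker's rounding; report tables here use the
    conventional half-up rule (2.345 -> 2.35).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
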