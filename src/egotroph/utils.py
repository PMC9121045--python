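"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (spreadsheet convention).

    Printed-precision comparisons use this rather than banker's rounding,
    so 0.45 stays 0.45 at two decimals and 33.335 rounds to 33.34.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
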