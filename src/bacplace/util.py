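"""Small shared numerics."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching how printed report
    tables are conventionally rounded (Python's built-in ``round``
    uses banker's rounding)."""
    q = Decimal("1").scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
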