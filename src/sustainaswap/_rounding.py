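"""Half-up decimal rounding for report-time formatting.

All internal arithmetic is carried unrounded; rounding happens only when a
number is written into a report or compared against a published table, and
then always half-up (0.5 rounds away from zero), matching how nutrition
tables are conventionally printed. Python's built-in ``round`` is
banker's rounding and would disagree on exact .5 boundaries.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
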