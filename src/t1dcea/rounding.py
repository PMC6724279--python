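"""Printed-value rounding helpers.

Internal arithmetic is carried at full floating precision everywhere; these
helpers exist only to reproduce *printed* figures, which use commercial
round-half-away-from-zero (e.g. a rate ratio of 10.5368 prints as 10.5 and a
maintenance cost of 29,673.0655... MXN prints as 29,673.07).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away", "money"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Python's builtin ``round`` uses banker's rounding, which does not
    reproduce tabulated currency/ratio figures.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def money(x: float) -> float:
    """Round a currency amount to centavos/cents (2 decimals, half away)."""
    return round_half_away(x, 2)
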