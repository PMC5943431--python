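"""Presentation rounding helpers.

All model arithmetic is carried out in full double precision; integers
appear only at presentation boundaries, rounded half-away-from-zero.
Inputs are first snapped to six decimals so that binary representation
dust (e.g. ``0.23 * 24050 == 5531.499999...``) cannot flip a half tie.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero; returns an int when ``ndigits == 0``."""
    snapped = Decimal(repr(round(float(x), 6)))
    exp = Decimal(1).scaleb(-ndigits)
    q = snapped.quantize(exp, rounding=ROUND_HALF_UP)
    return int(q) if ndigits == 0 else float(q)
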