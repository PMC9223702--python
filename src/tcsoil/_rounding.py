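"""Half-up decimal rounding for table display.

Printed tables in agronomy/soil-microbiology journals round half away from
zero (2.2325 -> 2.233), which is neither Python's built-in ``round`` (banker's
rounding) nor plain float quantisation.  Binary floats also under-represent
decimal .5 boundaries ((0.916 + 1.021) / 2 == 0.9684999...), so values are
first snapped to ``ndigits + 6`` decimals before the final half-up step.  The
guard digits mean a value that truly differs from a .5 boundary only beyond
the 6th extra decimal is treated as sitting on the boundary; for quantities
derived from 2-3 decimal table entries this is always the intended reading.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]

_GUARD = 6


def round_half_up(x: float, ndigits: int) -> float:
    """Round *x* to *ndigits* decimals, ties away from zero.

    >>> round_half_up(2.2325, 3)
    2.233
    >>> round_half_up((0.916 + 1.021) / 2, 3)
    0.969
    """
    if x != x:  # NaN propagates
        return x
    d = Decimal(repr(float(x)))
    snapped = d.quantize(Decimal(1).scaleb(-(ndigits + _GUARD)), rounding=ROUND_HALF_UP)
    return float(snapped.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
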