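"""Shared rounding rules used by every printed number in the toolkit."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half-up (0.5 rounds away from zero toward +inf).

    Python's built-in :func:`round` uses banker's rounding; all percentages
    and headline rates in this package round half-up instead.
    """
    scale = 10**ndigits
    result = math.floor(x * scale + 0.5) / scale
    return int(result) if ndigits == 0 else result


def percent(numerator: int, denominator: int) -> int:
    """Integer percent ``100 * numerator / denominator``, rounded half-up.

    Defined as 0 when ``denominator`` is 0.  Computed in exact integer
    arithmetic so that printed-table checks never hinge on float error.

    Raises
    ------
    ValueError
        If counts are negative or ``numerator > denominator``.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    if numerator > denominator:
        raise ValueError(
            f"numerator {numerator} exceeds denominator {denominator}"
        )
    if denominator == 0:
        return 0
    # floor((100*n/d) + 1/2) without floats
    return (200 * numerator + denominator) // (2 * denominator)
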