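"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (printed-table convention).

    Python's builtin ``round`` uses banker's rounding, which disagrees with
    how percentages are conventionally printed (e.g. 86.75 -> 86.8).
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    scaled = x * factor
    return math.floor(abs(scaled) + 0.5) / factor * (1 if scaled >= 0 else -1)


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``numerator / denominator * 100`` rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(numerator / denominator * 100.0, ndigits)
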