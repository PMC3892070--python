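"""Small shared numeric helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_up", "percent_of"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    Python's built-in ``round`` uses banker's rounding (2.5 -> 2); report
    percentages and imputed day-counts instead follow the everyday half-up
    convention (2.5 -> 3). Inputs here are ratios of modest integers, for
    which ``floor(x + 0.5)`` is exact.
    """
    return int(math.floor(x + 0.5))


def percent_of(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    return round_half_up(100.0 * numerator / denominator)
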