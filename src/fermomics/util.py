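"""Small shared helpers."""

from __future__ import annotations


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Share of a cohort as a percentage, rounded for reporting
    (e.g. 8 of 115 participants -> 7.0)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round(100.0 * numerator / denominator, ndigits)
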