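"""Reporting helpers: percentages, filter-cascade tables."""

from __future__ import annotations

import pandas as pd

__all__ = ["fraction_percent", "format_fraction", "cascade_table"]


def fraction_percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """A count ratio as a percentage rounded to ``digits`` decimals.

    ``fraction_percent(32, 47)`` -> 68.1.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return round(100.0 * numerator / denominator, digits)


def format_fraction(numerator: int, denominator: int, digits: int = 1) -> str:
    pct = fraction_percent(numerator, denominator, digits)
    return f"{numerator}/{denominator} ({pct:.{digits}f}%)"


def cascade_table(stage_counts: list[tuple[str, int]]) -> pd.DataFrame:
    """Per-filter survivor counts with the fraction of the initial cohort.

    ``stage_counts`` is an ordered list of (stage name, surviving count);
    counts must be nonincreasing.
    """
    if not stage_counts:
        return pd.DataFrame(columns=["stage", "count", "pct_of_initial"])
    counts = [c for _, c in stage_counts]
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("filter cascade counts must be nonincreasing")
    initial = counts[0]
    rows = [
        (name, c, fraction_percent(c, initial) if initial else 0.0)
        for name, c in stage_counts
    ]
    return pd.DataFrame(rows, columns=["stage", "count", "pct_of_initial"])
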