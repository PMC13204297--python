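"""Derivative indicators: annual-change posterior contrast, sex gaps, and
threshold/count/range summaries over reference or computed tables.

Count and range operations run on prefecture-level columns (nationwide is
excluded by the callers via `FixtureTable.column`); threshold comparisons are
inclusive, so a value printed exactly at the cutoff counts as meeting it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws, inverse_logit


@dataclass(frozen=True)
class ApcSummary:
    """Posterior mean and 95% interval of the annual change in percentage points."""

    mean: float
    cri_low: float
    cri_high: float


@dataclass(frozen=True)
class DisparityRecord:
    unit: str
    metric: str
    men_value: float
    women_value: float

    @property
    def diff(self) -> float:
        return self.men_value - self.women_value


def apc_draws(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw annual change: 100 * (invlogit(alpha + beta) - invlogit(alpha))."""
    return 100.0 * (inverse_logit(draws.alpha + draws.beta) - inverse_logit(draws.alpha))


def apc(draws: PosteriorDraws) -> ApcSummary:
    """Annual percentage-point change summarized from the posterior draws."""
    d = apc_draws(draws)
    lo, hi = np.percentile(d, [2.5, 97.5])
    return ApcSummary(mean=float(d.mean()), cri_low=float(lo), cri_high=float(hi))


def sex_gap(men: float, women: float) -> float:
    """Male minus female value in percentage points, at 1-decimal reporting resolution."""
    return round(men - women, 1)


def count_meeting_threshold(column: pd.Series, threshold: float) -> tuple[int, list[str]]:
    """Units whose value is at or above ``threshold`` (inclusive comparison)."""
    hits = column[column >= threshold]
    return len(hits), list(hits.index)


def count_large_disparity(
    men: pd.Series, women: pd.Series, cutoff: float
) -> tuple[int, list[str]]:
    """Units where 100 * (men - women) meets or exceeds ``cutoff`` percentage points.

    Inputs are probability columns on the [0, 1] scale, indexed by unit.
    """
    diff = 100.0 * (men - women.reindex(men.index))
    hits = diff[diff >= cutoff]
    return len(hits), list(hits.index)


def range_summary(column: pd.Series) -> tuple[tuple[str, float], tuple[str, float]]:
    """(min unit+value, max unit+value); ties broken by table order."""
    if column.empty:
        raise ValueError("empty column")
    imin = int(np.argmin(column.to_numpy()))
    imax = int(np.argmax(column.to_numpy()))
    return (
        (str(column.index[imin]), float(column.iloc[imin])),
        (str(column.index[imax]), float(column.iloc[imax])),
    )


def change_summary(col_a: pd.Series, col_b: pd.Series) -> pd.Series:
    """Per-unit difference col_b - col_a in percentage points; unit sets must match."""
    if set(col_a.index) != set(col_b.index):
        raise ValueError("mismatched unit sets")
    return (col_b - col_a.reindex(col_b.index)).round(1)
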