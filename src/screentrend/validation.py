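"""Holdout forecast validation: train on early waves, predict the held-out wave,
and aggregate the five accuracy metrics across unit-sex pairs.

Errors are predicted minus observed on the percent scale, so a positive bias
means over-prediction.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import CoverageSeries
from .model import McmcConfig, PriorSpec, fit_trend
from .projection import project_coverage, projected_draws


@dataclass(frozen=True)
class ValidationMetrics:
    """MAD/RMSD/bias in percentage points, MAPD in percent, interval coverage as a fraction."""

    mad: float
    rmsd: float
    bias: float
    mapd: float
    interval_coverage: float
    n_units: int


def metrics_from_residual_table(table: pd.DataFrame) -> ValidationMetrics:
    """Aggregate a per-unit residual table (percent-scale columns) into the five metrics."""
    err = (table["predicted_pct"] - table["observed_pct"]).to_numpy()
    obs = table["observed_pct"].to_numpy()
    inside = (
        (table["observed_pct"] >= table["cri_low_pct"])
        & (table["observed_pct"] <= table["cri_high_pct"])
    ).to_numpy()
    return ValidationMetrics(
        mad=float(np.mean(np.abs(err))),
        rmsd=float(np.sqrt(np.mean(err**2))),
        bias=float(np.mean(err)),
        mapd=float(np.mean(np.abs(err) / obs) * 100.0),
        interval_coverage=float(np.mean(inside)),
        n_units=len(table),
    )


def holdout_validate(
    dataset: Sequence[CoverageSeries],
    train_years: Iterable[int],
    test_year: int,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    add_noise: bool = False,
    point: str = "mean",
) -> tuple[ValidationMetrics, pd.DataFrame]:
    """Fit each series on ``train_years`` only and score predictions at ``test_year``.

    Series missing any training wave or the test wave are skipped with a
    warning and excluded from ``n_units``. The point prediction is the
    posterior mean of projected coverage (``point="median"`` for the median).
    """
    train = sorted(set(int(y) for y in train_years))
    config = config or McmcConfig()
    rows = []
    for series in dataset:
        have = set(series.years)
        if not set(train) <= have or test_year not in have:
            warnings.warn(
                f"series ({series.unit}, {series.sex}) missing required waves; skipped",
                stacklevel=2,
            )
            continue
        obs_by_year = {o.year: o for o in series.observations}
        train_series = CoverageSeries(
            series.unit, series.sex, [obs_by_year[y] for y in train]
        )
        seed = config.seed + zlib.crc32(f"{series.unit}|{series.sex}".encode()) % 100_000
        draws, _ = fit_trend(
            train_series,
            priors,
            McmcConfig(
                chains=config.chains,
                iterations=config.iterations,
                burn_in=config.burn_in,
                seed=seed,
                target_accept=config.target_accept,
                adapt_window=config.adapt_window,
            ),
        )
        summary = project_coverage(draws, test_year, add_noise=add_noise)
        pred = (
            summary.mean
            if point == "mean"
            else float(np.median(projected_draws(draws, test_year)))
        )
        rows.append(
            {
                "unit": series.unit,
                "sex": series.sex,
                "observed_pct": obs_by_year[test_year].coverage * 100.0,
                "predicted_pct": pred * 100.0,
                "cri_low_pct": summary.cri_low * 100.0,
                "cri_high_pct": summary.cri_high * 100.0,
            }
        )
    if not rows:
        raise ValueError("no series had all required waves")
    table = pd.DataFrame(rows)
    table["error_pct"] = table["predicted_pct"] - table["observed_pct"]
    return metrics_from_residual_table(table), table
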