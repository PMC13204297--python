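"""Posterior projection of coverage, benchmark exceedance, and target-year search."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import NEVER
from .model import PosteriorDraws, inverse_logit

HORIZON_YEAR = 2028
TARGET_THRESHOLD = 0.60
ON_TRACK_PROB = 0.80
ON_TRACK_YEAR = 2030
HORIZON_MAX = 2100


@dataclass(frozen=True)
class ProjectionSummary:
    """Posterior mean and equal-tailed 95% interval of projected coverage."""

    year: int
    mean: float
    cri_low: float
    cri_high: float


@dataclass(frozen=True)
class TargetAttainment:
    """Exceedance probability at the horizon plus both on-track conventions."""

    prob_at_horizon: float
    target_year: int | str
    on_track_prob: bool
    on_track_year: bool


def projected_draws(draws: PosteriorDraws, year: int, add_noise: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-draw projected coverage at ``year`` via the inverse-logit linear predictor.

    By default only the linear predictor is transformed (no residual noise);
    ``add_noise=True`` adds Normal(0, sigma) observation noise per draw for
    sensitivity checks.
    """
    offset = year - draws.center_year
    eta = draws.alpha + draws.beta * offset
    if add_noise:
        rng = rng or np.random.default_rng(0)
        eta = eta + draws.sigma * rng.standard_normal(len(draws))
    return inverse_logit(eta)


def project_coverage(draws: PosteriorDraws, year: int, add_noise: bool = False) -> ProjectionSummary:
    """Summarize projected coverage at ``year`` (mean, 2.5/97.5 percentiles)."""
    if year < draws.center_year:
        raise ValueError(f"projection year {year} precedes center year {draws.center_year}")
    p = projected_draws(draws, year, add_noise=add_noise)
    lo, hi = np.percentile(p, [2.5, 97.5])
    return ProjectionSummary(year=int(year), mean=float(p.mean()), cri_low=float(lo), cri_high=float(hi))


def exceedance_prob(draws: PosteriorDraws, year: int, threshold: float = TARGET_THRESHOLD) -> float:
    """Fraction of posterior draws whose projected coverage meets or exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return float(np.mean(projected_draws(draws, year) >= threshold))


def target_year(
    draws: PosteriorDraws,
    threshold: float = TARGET_THRESHOLD,
    prob_level: float = ON_TRACK_PROB,
    horizon_max: int = HORIZON_MAX,
    strict: bool = False,
) -> int | str:
    """First year on the annual grid where the exceedance probability reaches ``prob_level``.

    Scans calendar years from the centering year through ``horizon_max``
    inclusive; returns the "never" sentinel if the level is not reached.
    ``strict=True`` requires the probability to strictly exceed the level.
    """
    if not 0.0 < prob_level < 1.0:
        raise ValueError("prob_level must lie in (0, 1)")
    for year in range(draws.center_year, horizon_max + 1):
        p = exceedance_prob(draws, year, threshold)
        if (p > prob_level) if strict else (p >= prob_level):
            return year
    return NEVER


def classify_attainment(
    draws: PosteriorDraws,
    horizon: int = HORIZON_YEAR,
    threshold: float = TARGET_THRESHOLD,
    prob_level: float = ON_TRACK_PROB,
    horizon_max: int = HORIZON_MAX,
    on_track_by: int = ON_TRACK_YEAR,
) -> TargetAttainment:
    """Attainment probability at the horizon and both on-track rules.

    ``on_track_prob`` applies the inclusive >= 0.80 probability rule at the
    horizon year; ``on_track_year`` flags a target year at or before 2030.
    """
    prob = exceedance_prob(draws, horizon, threshold)
    ty = target_year(draws, threshold, prob_level, horizon_max)
    return TargetAttainment(
        prob_at_horizon=prob,
        target_year=ty,
        on_track_prob=prob >= prob_level,
        on_track_year=(ty != NEVER and ty <= on_track_by),
    )
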