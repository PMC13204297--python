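import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screentrend.data import NEVER
from screentrend.model import PosteriorDraws, inverse_logit, logit
from screentrend.projection import (
    classify_attainment,
    exceedance_prob,
    project_coverage,
    projected_draws,
    target_year,
)

from conftest import constant_draws


def brute_force_target_year(draws, threshold, prob_level, horizon_max):
    """Independent oracle: explicit exceedance counts on the annual grid."""
    for year in range(draws.center_year, horizon_max + 1):
        p = inverse_logit(draws.alpha + draws.beta * (year - draws.center_year))
        if np.count_nonzero(p >= threshold) / len(p) >= prob_level:
            return year
    return NEVER


class TestProjectCoverage:
    def test_degenerate_draws_one_year_out(self):
        draws = constant_draws(alpha=0.0, beta=0.1)
        summary = project_coverage(draws, draws.center_year + 1)
        # oracle: direct evaluation 1 / (1 + exp(-0.1))
        assert summary.mean == pytest.approx(1 / (1 + np.exp(-0.1)), abs=1e-12)
        assert summary.mean == pytest.approx(0.52498, abs=5e-6)
        assert summary.cri_low == pytest.approx(summary.cri_high, abs=1e-12)

    def test_center_year_is_inverse_logit_alpha(self):
        rng = np.random.default_rng(0)
        draws = PosteriorDraws(
            alpha=rng.normal(-0.3, 0.1, 5000),
            beta=rng.normal(0.03, 0.01, 5000),
            sigma=np.full(5000, 0.05),
            center_year=2013,
        )
        p = projected_draws(draws, 2013)
        assert np.array_equal(p, inverse_logit(draws.alpha))

    def test_rejects_year_before_center(self):
        with pytest.raises(ValueError):
            project_coverage(constant_draws(0, 0.1), 2012)

    def test_horizon_is_six_years_past_final_wave(self):
        # 2028 = final observation 2022 + two triennial intervals
        assert 2028 - 2022 == 6
        draws = constant_draws(alpha=logit(0.497), beta=0.03, n=100)
        summary = project_coverage(draws, 2028)
        expected = inverse_logit(logit(0.497) + 0.03 * (2028 - 2013))
        assert summary.mean == pytest.approx(expected, abs=1e-12)


class TestExceedance:
    def test_all_above(self):
        draws = constant_draws(alpha=logit(0.7), beta=0.0)
        assert exceedance_prob(draws, 2020, 0.60) == 1.0

    def test_symmetric_at_threshold(self):
        rng = np.random.default_rng(1)
        draws = PosteriorDraws(
            alpha=logit(0.6) + rng.standard_normal(20000) * 0.2,
            beta=np.zeros(20000),
            sigma=np.full(20000, 0.05),
            center_year=2013,
        )
        assert exceedance_prob(draws, 2028, 0.60) == pytest.approx(0.5, abs=0.02)

    def test_counting_oracle(self):
        rng = np.random.default_rng(2)
        n = 30_000
        draws = PosteriorDraws(
            alpha=rng.normal(-0.3, 0.3, n),
            beta=rng.normal(0.03, 0.02, n),
            sigma=np.full(n, 0.05),
            center_year=2013,
        )
        p = inverse_logit(draws.alpha + draws.beta * 15)
        k = int(np.count_nonzero(p >= 0.60))
        assert exceedance_prob(draws, 2028, 0.60) == pytest.approx(k / n, abs=1e-12)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        draws = PosteriorDraws(
            alpha=rng.normal(0, 0.5, 5000),
            beta=rng.normal(0.02, 0.02, 5000),
            sigma=np.full(5000, 0.05),
            center_year=2013,
        )
        probs = [exceedance_prob(draws, 2028, t) for t in (0.3, 0.5, 0.6, 0.7, 0.9)]
        assert probs == sorted(probs, reverse=True)

    def test_monotone_in_year_when_slopes_positive(self):
        rng = np.random.default_rng(4)
        draws = PosteriorDraws(
            alpha=rng.normal(-0.5, 0.3, 5000),
            beta=np.abs(rng.normal(0.03, 0.02, 5000)),
            sigma=np.full(5000, 0.05),
            center_year=2013,
        )
        probs = [exceedance_prob(draws, y, 0.6) for y in range(2013, 2060, 5)]
        assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            exceedance_prob(constant_draws(0, 0), 2020, 0.0)


class TestTargetYear:
    def test_already_above_at_center(self):
        draws = constant_draws(alpha=logit(0.7), beta=0.0, center_year=2013)
        assert target_year(draws) == 2013

    def test_never_for_nonpositive_slopes_below_threshold(self):
        rng = np.random.default_rng(5)
        draws = PosteriorDraws(
            alpha=logit(0.4) + 0.05 * rng.standard_normal(2000),
            beta=-np.abs(rng.normal(0.01, 0.005, 2000)),
            sigma=np.full(2000, 0.05),
            center_year=2013,
        )
        assert target_year(draws) == NEVER

    def test_crossing_between_offsets_matches_grid_oracle(self):
        # constructed so the 0.80 crossing lands between offsets 14 and 15
        rng = np.random.default_rng(6)
        n = 10_000
        draws = PosteriorDraws(
            alpha=rng.normal(logit(0.45), 0.05, n),
            beta=rng.normal(0.051, 0.012, n),
            sigma=np.full(n, 0.05),
            center_year=2013,
        )
        oracle = brute_force_target_year(draws, 0.60, 0.80, 2100)
        p14 = exceedance_prob(draws, 2013 + 14, 0.60)
        p15 = exceedance_prob(draws, 2013 + 15, 0.60)
        assert p14 < 0.80 <= p15, "construction check"
        assert oracle == 2013 + 15
        assert target_year(draws) == oracle

    def test_matches_oracle_on_random_draw_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 500
            draws = PosteriorDraws(
                alpha=rng.normal(-0.5, 0.4, n),
                beta=rng.normal(0.02, 0.03, n),
                sigma=np.full(n, 0.05),
                center_year=2013,
            )
            assert target_year(draws) == brute_force_target_year(draws, 0.60, 0.80, 2100)

    def test_non_increasing_as_prob_level_decreases(self):
        rng = np.random.default_rng(8)
        draws = PosteriorDraws(
            alpha=rng.normal(-0.3, 0.2, 3000),
            beta=np.abs(rng.normal(0.03, 0.01, 3000)),
            sigma=np.full(3000, 0.05),
            center_year=2013,
        )
        years = []
        for level in (0.95, 0.8, 0.5, 0.2):
            ty = target_year(draws, prob_level=level)
            years.append(2101 if ty == NEVER else ty)
        assert years == sorted(years, reverse=True)

    def test_strict_vs_inclusive(self):
        draws = constant_draws(alpha=logit(0.7), beta=0.0)
        # all mass above the threshold: inclusive hits at exactly 1.0 >= 0.8 either way
        assert target_year(draws, prob_level=0.8, strict=True) == draws.center_year
        # probability exactly at the level: inclusive attains, strict does not
        rng = np.random.default_rng(9)
        n = 10
        alpha = np.where(np.arange(n) < 8, logit(0.7), logit(0.3))
        d2 = PosteriorDraws(
            alpha=alpha, beta=np.zeros(n), sigma=np.full(n, 0.05), center_year=2013
        )
        assert target_year(d2, prob_level=0.8) == 2013
        assert target_year(d2, prob_level=0.8, strict=True) == NEVER


class TestClassify:
    def test_on_track_prob(self):
        draws = constant_draws(alpha=logit(0.65), beta=0.01)
        att = classify_attainment(draws)
        assert att.prob_at_horizon == 1.0
        assert att.on_track_prob and att.on_track_year

    def test_year_rule_without_prob_rule(self):
        # crossing shortly after the horizon: on-track by year, not by probability
        rng = np.random.default_rng(10)
        n = 20_000
        draws = PosteriorDraws(
            alpha=rng.normal(logit(0.50), 0.02, n),
            beta=rng.normal(0.030, 0.006, n),
            sigma=np.full(n, 0.05),
            center_year=2013,
        )
        att = classify_attainment(draws)
        if not att.on_track_prob and att.target_year != NEVER:
            assert att.prob_at_horizon < 0.80
            assert att.on_track_year == (att.target_year <= 2030)

    def test_exactly_at_level_is_on_track(self):
        n = 10
        alpha = np.where(np.arange(n) < 8, logit(0.7), logit(0.3))
        draws = PosteriorDraws(
            alpha=alpha, beta=np.zeros(n), sigma=np.full(n, 0.05), center_year=2013
        )
        att = classify_attainment(draws)
        assert att.prob_at_horizon == pytest.approx(0.80, abs=1e-12)
        assert att.on_track_prob  # inclusive ">= 0.80" rule

    def test_consistency_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = 400
            draws = PosteriorDraws(
                alpha=rng.normal(-0.2, 0.4, n),
                beta=rng.normal(0.02, 0.03, n),
                sigma=np.full(n, 0.05),
                center_year=2013,
            )
            att = classify_attainment(draws)
            if att.on_track_year:
                assert att.target_year != NEVER and att.target_year <= 2030
            if att.on_track_prob:
                assert exceedance_prob(draws, 2028, 0.60) >= 0.80
            if att.target_year != NEVER and att.target_year <= 2028:
                assert att.prob_at_horizon >= 0.80

    @given(st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=20, deadline=None)
    def test_probability_in_unit_interval(self, frac):
        rng = np.random.default_rng(12)
        n = 200
        draws = PosteriorDraws(
            alpha=rng.normal(logit(frac), 0.3, n),
            beta=rng.normal(0.0, 0.02, n),
            sigma=np.full(n, 0.05),
            center_year=2013,
        )
        p = exceedance_prob(draws, 2028, 0.6)
        assert 0.0 <= p <= 1.0
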