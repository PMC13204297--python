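import numpy as np
import pytest

from screentrend.data import CoverageObservation, CoverageSeries
from screentrend.model import McmcConfig


def make_series(
    coverages, years=(2013, 2016, 2019, 2022), unit="u", sex="total"
) -> CoverageSeries:
    obs = [CoverageObservation(unit, sex, y, c) for y, c in zip(years, coverages)]
    return CoverageSeries(unit, sex, obs)


@pytest.fixture(scope="session")
def fixture_table():
    from screentrend.data import load_fixture_tables

    return load_fixture_tables()


@pytest.fixture
def fast_config():
    """Short chains for tests that only need a roughly correct posterior."""
    return McmcConfig(chains=3, iterations=1500, burn_in=500, seed=0)


@pytest.fixture
def nationwide_series():
    """4-wave series with the printed national endpoints and plausible middles."""
    return make_series([0.423, 0.45, 0.47, 0.497], unit="nationwide")


def constant_draws(alpha, beta, n=1000, sigma=0.05, center_year=2013, **kw):
    from screentrend.model import PosteriorDraws

    return PosteriorDraws(
        alpha=np.full(n, float(alpha)),
        beta=np.full(n, float(beta)),
        sigma=np.full(n, float(sigma)),
        center_year=center_year,
        **kw,
    )
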