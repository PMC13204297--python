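"""Logit-scale Bayesian linear trend fitting for a single coverage series.

Model: logit(coverage) = alpha + beta * (year - center_year) + eps,
eps ~ Normal(0, sigma^2), fitted by an adaptive random-walk Metropolis
sampler on (alpha, beta, log sigma). The proposal covariance is adapted
during burn-in only, so the retained draws come from a fixed-kernel chain.

A conjugate normal-inverse-gamma closed form (`conjugate_posterior`) is
provided as an independent oracle for the vague-prior limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit as _logit

from .data import CoverageSeries


def logit(p):
    """Natural-log odds ln(p / (1 - p)); domain error outside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires 0 < p < 1")
    out = _logit(p)
    return float(out) if out.ndim == 0 else out


def inverse_logit(x):
    """Logistic function 1 / (1 + exp(-x)), the inverse of `logit`."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def center_years(series: CoverageSeries) -> tuple[np.ndarray, int]:
    """Offsets (year - center) with the earliest training year as center.

    The baseline wave gets offset 0, which decorrelates intercept and slope.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    years = np.asarray(series.years, dtype=float)
    center = int(years.min())
    return years - center, center


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors on the logit scale.

    Defaults span coverage roughly 7%-93% at +/-1 intercept sd and allow
    implausibly steep annual trends at +/-1 slope sd. ``residual_sd_scale``
    is the scale of a half-Normal prior on sigma.
    """

    intercept_mean: float = 0.0
    intercept_sd: float = 2.5
    slope_mean: float = 0.0
    slope_sd: float = 1.0
    residual_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.intercept_sd <= 0 or self.slope_sd <= 0 or self.residual_sd_scale <= 0:
            raise ValueError("prior sd/scale parameters must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings. Defaults reproduce 3 x (12,000 - 2,000) = 30,000 pooled draws."""

    chains: int = 3
    iterations: int = 12_000
    burn_in: int = 2_000
    seed: int = 0
    target_accept: float = 0.30
    adapt_window: int = 100

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")

    @property
    def kept_per_chain(self) -> int:
        return self.iterations - self.burn_in


@dataclass
class PosteriorDraws:
    """Pooled posterior draws of (alpha, beta, sigma) plus the centering year."""

    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    center_year: int
    unit: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        if not (len(self.alpha) == len(self.beta) == len(self.sigma)):
            raise ValueError("draw vectors must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma draws must be strictly positive")

    def __len__(self) -> int:
        return len(self.alpha)


@dataclass
class ConvergenceReport:
    """Split-chain potential-scale-reduction per parameter plus acceptance rates."""

    rhat: dict[str, float] = field(default_factory=dict)
    acceptance_rate: list[float] = field(default_factory=list)
    threshold: float = 1.01

    @property
    def converged(self) -> bool:
        return all(
            math.isfinite(v) and v <= self.threshold for v in self.rhat.values()
        )

    @property
    def flagged(self) -> list[str]:
        return [k for k, v in self.rhat.items() if not (math.isfinite(v) and v <= self.threshold)]


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws). Each chain is split in half,
    then the classic between/within variance ratio is computed on the
    2 * n_chains half-chains. Returns >= 1 (up to floating point) for any
    well-defined input; NaN if draws are constant.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    # the finite-sample estimator can dip below 1; floor it so the statistic
    # is >= 1 by construction
    return float(max(1.0, np.sqrt(var_plus / w)))


def check_convergence(
    per_chain: dict[str, np.ndarray],
    acceptance_rate: list[float] | None = None,
    threshold: float = 1.01,
) -> ConvergenceReport:
    """Numeric convergence diagnostic over per-parameter (n_chains, n_draws) arrays."""
    report = ConvergenceReport(acceptance_rate=list(acceptance_rate or []), threshold=threshold)
    for name, arr in per_chain.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] < 2:
            warnings.warn(
                "split-chain diagnostic needs >= 2 chains; statistic unavailable",
                stacklevel=2,
            )
            report.rhat[name] = float("nan")
            continue
        report.rhat[name] = split_rhat(arr)
    return report


def default_log_prior(theta: np.ndarray, priors: PriorSpec) -> np.ndarray:
    """Log prior on (alpha, beta, log sigma) including the log-sigma Jacobian.

    Independent normals on alpha and beta, half-Normal on sigma.
    """
    alpha, beta, log_sigma = theta[:, 0], theta[:, 1], theta[:, 2]
    sigma = np.exp(log_sigma)
    return (
        -0.5 * ((alpha - priors.intercept_mean) / priors.intercept_sd) ** 2
        - 0.5 * ((beta - priors.slope_mean) / priors.slope_sd) ** 2
        - 0.5 * (sigma / priors.residual_sd_scale) ** 2
        + log_sigma  # Jacobian of the sigma -> log sigma reparametrization
    )


def _log_posterior(
    theta: np.ndarray, x: np.ndarray, y: np.ndarray, log_prior
) -> np.ndarray:
    """Unnormalized log posterior on (alpha, beta, log sigma); theta is (chains, 3)."""
    alpha, beta, log_sigma = theta[:, 0], theta[:, 1], theta[:, 2]
    n = len(y)
    # extreme proposals overflow harmlessly; NaN/inf map to log density -inf
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        sigma = np.exp(log_sigma)
        resid = y[None, :] - alpha[:, None] - beta[:, None] * x[None, :]
        loglik = -n * log_sigma - 0.5 * np.sum(resid**2, axis=1) / sigma**2
        lp = loglik + log_prior(theta)
    return np.where(np.isnan(lp), -np.inf, lp)


class _Whitening:
    """Map between sampler coordinates and model parameters.

    The posterior of (alpha, beta, log sigma) is funnel-shaped: the
    conditional scale of the regression coefficients is proportional to
    sigma. The sampler therefore walks in whitened coordinates
    v = (w1, w2, u) with

        (alpha, beta) = ols + exp(u) * L w,   log sigma = u,

    where L is the Cholesky factor of (X'X)^-1, so the coefficient block is
    approximately standard normal at every sigma level. The target picks up
    the Jacobian exp(2u) of the state-dependent linear map.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray) -> None:
        X = np.column_stack([np.ones_like(x), x])
        xtx = X.T @ X
        if np.linalg.matrix_rank(xtx) < 2:
            raise ValueError("degenerate design: need at least 2 distinct years")
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        self.ols = coef
        self.L = np.linalg.cholesky(np.linalg.inv(xtx))
        dof = max(len(y) - 2, 1)
        rss = float(res[0]) if res.size else float(np.sum((y - X @ coef) ** 2))
        self.sigma0 = math.sqrt(max(rss / dof, 1e-4))

    def to_theta(self, v: np.ndarray) -> np.ndarray:
        """(chains, 3) whitened state -> (alpha, beta, log sigma)."""
        theta = np.empty_like(v)
        scale = np.exp(v[:, 2])
        theta[:, 0] = self.ols[0] + scale * (self.L[0, 0] * v[:, 0])
        theta[:, 1] = self.ols[1] + scale * (self.L[1, 0] * v[:, 0] + self.L[1, 1] * v[:, 1])
        theta[:, 2] = v[:, 2]
        return theta

    def initial(self, chains: int, rng: np.random.Generator) -> np.ndarray:
        """Overdispersed starts around the least-squares fit."""
        v = np.empty((chains, 3))
        v[:, 0] = 2.0 * rng.standard_normal(chains)
        v[:, 1] = 2.0 * rng.standard_normal(chains)
        v[:, 2] = math.log(self.sigma0) + 0.5 * rng.standard_normal(chains)
        return v


def fit_trend(
    series: CoverageSeries,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    log_prior=None,
) -> tuple[PosteriorDraws, ConvergenceReport]:
    """Fit the logit-linear trend model by adaptive random-walk Metropolis.

    All chains advance in lockstep with a joint Gaussian proposal whose
    covariance is re-estimated from each chain's own recent history every
    ``adapt_window`` iterations during burn-in, with a Robbins-Monro scale
    correction toward ``target_accept``. Adaptation freezes at the end of
    burn-in. Identical (series, priors, config) give bit-identical draws.

    ``log_prior`` optionally replaces the default prior: a callable taking
    the (chains, 3) state on (alpha, beta, log sigma) and returning the log
    prior density per chain, Jacobian included (see `default_log_prior`).
    Used by tests to target conjugate posteriors with a known closed form.
    """
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    if log_prior is None:
        log_prior = lambda theta: default_log_prior(theta, priors)  # noqa: E731
    if len(series) < 2:
        raise ValueError("need at least 2 observations to fit a trend")
    x, center = center_years(series)
    y = logit(np.asarray(series.coverages))
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite logit-transformed coverage")

    nchains, niter, nburn = config.chains, config.iterations, config.burn_in
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    white = _Whitening(x, y)
    v = white.initial(nchains, rng)
    jac = 2.0 * v[:, 2]  # log|d theta / d v| of the whitened map
    lp = _log_posterior(white.to_theta(v), x, y, log_prior) + jac

    # per-chain proposal state: Cholesky factor and log step scale
    chol = np.tile(np.diag([1.0, 1.0, 0.5]), (nchains, 1, 1))
    log_scale = np.zeros(nchains)
    window_accepts = np.zeros(nchains)
    total_accepts = np.zeros(nchains)
    history = np.empty((nburn, nchains, 3)) if nburn else None
    kept = np.empty((config.kept_per_chain, nchains, 3))

    for it in range(niter):
        z = rng.standard_normal((nchains, 3))
        step = np.exp(log_scale)[:, None] * np.einsum("cij,cj->ci", chol, z)
        prop = v + step
        lp_prop = _log_posterior(white.to_theta(prop), x, y, log_prior) + 2.0 * prop[:, 2]
        accept = np.log(rng.uniform(size=nchains)) < lp_prop - lp
        v = np.where(accept[:, None], prop, v)
        lp = np.where(accept, lp_prop, lp)
        window_accepts += accept
        if it >= nburn:
            total_accepts += accept
            kept[it - nburn] = v
        else:
            history[it] = v
            if (it + 1) % config.adapt_window == 0:
                window = (it + 1) // config.adapt_window
                rate = window_accepts / config.adapt_window
                window_accepts[:] = 0.0
                gamma = window**-0.6
                log_scale += gamma * (rate - config.target_accept)
                if window >= 3:
                    # discard the first half of the history as transient
                    lo = (it + 1) // 2
                    for c in range(nchains):
                        cov = np.cov(history[lo : it + 1, c, :], rowvar=False)
                        cov = (2.38**2 / 3.0) * cov + 1e-10 * np.eye(3)
                        try:
                            chol[c] = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass

    theta_kept = white.to_theta(kept.reshape(-1, 3)).reshape(kept.shape)
    per_chain = {
        "alpha": theta_kept[:, :, 0].T,
        "beta": theta_kept[:, :, 1].T,
        "sigma": np.exp(theta_kept[:, :, 2]).T,
    }
    acc_rates = (total_accepts / config.kept_per_chain).tolist()
    if nchains >= 2:
        report = check_convergence(per_chain, acceptance_rate=acc_rates)
    else:
        report = ConvergenceReport(
            rhat={k: float("nan") for k in per_chain}, acceptance_rate=acc_rates
        )
    draws = PosteriorDraws(
        alpha=per_chain["alpha"].reshape(-1),
        beta=per_chain["beta"].reshape(-1),
        sigma=per_chain["sigma"].reshape(-1),
        center_year=center,
        unit=series.unit,
        sex=series.sex,
    )
    return draws, report


def nig_log_prior(
    v0_diag: tuple[float, float] = (1e8, 1e8), a0: float = -0.5, b0: float = 0.0
):
    """Log prior (on the sampler's (alpha, beta, log sigma) state) for the
    normal-inverse-gamma family of `conjugate_posterior`.

    (alpha, beta) | sigma^2 ~ N(0, sigma^2 diag(v0_diag)),
    sigma^2 ~ InvGamma(a0, b0). Returned callable includes the Jacobian of
    the log-sigma parametrization, so passing it as ``log_prior`` to
    `fit_trend` makes the sampler target exactly the posterior whose
    marginal moments `conjugate_posterior` computes in closed form.
    """
    v0a, v0b = v0_diag

    def lp(theta: np.ndarray) -> np.ndarray:
        alpha, beta, u = theta[:, 0], theta[:, 1], theta[:, 2]
        return -(2.0 * a0 + 2.0) * u - (
            0.5 * (alpha**2 / v0a + beta**2 / v0b) + b0
        ) * np.exp(-2.0 * u)

    return lp


@dataclass(frozen=True)
class ConjugatePosterior:
    """Closed-form normal-inverse-gamma posterior summary for the linear model."""

    mean_alpha: float
    mean_beta: float
    sd_alpha: float
    sd_beta: float
    df: float


def conjugate_posterior(
    x: np.ndarray,
    y: np.ndarray,
    v0_diag: tuple[float, float] = (1e8, 1e8),
    a0: float = -0.5,
    b0: float = 0.0,
) -> ConjugatePosterior:
    """Analytic posterior for y = a + b x + Normal(0, sigma^2) noise.

    Prior: (a, b) | sigma^2 ~ N(0, sigma^2 V0), sigma^2 ~ InvGamma(a0, b0).
    The defaults (huge V0, a0 = -1/2, b0 = 0) correspond to a prior flat in
    (a, b, sigma), matching the vague limit of the sampler's independent
    normal + half-normal priors; the marginal on (a, b) is then Student-t
    with df = 2 a_n > 2, so posterior sds are finite even at n = 4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones_like(x), x])
    v0_inv = np.diag([1.0 / v0_diag[0], 1.0 / v0_diag[1]])
    vn_inv = v0_inv + X.T @ X
    vn = np.linalg.inv(vn_inv)
    mn = vn @ (X.T @ y)
    an = a0 + n / 2.0
    bn = b0 + 0.5 * (y @ y - mn @ vn_inv @ mn)
    if an <= 1:
        raise ValueError("posterior df too small for finite variance")
    df = 2.0 * an
    scale = (bn / an) * vn
    var = df / (df - 2.0) * np.diag(scale)
    return ConjugatePosterior(
        mean_alpha=float(mn[0]),
        mean_beta=float(mn[1]),
        sd_alpha=float(np.sqrt(var[0])),
        sd_beta=float(np.sqrt(var[1])),
        df=df,
    )
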