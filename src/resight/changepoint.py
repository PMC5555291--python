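"""Base Bayesian certain/uncertain change-point model.

Certain and uncertain sightings are parallel stationary Poisson processes,
discretised to per-year Bernoulli occupancy.  Before (or at) the extinction
year tau the certain process fires with probability ``1 - exp(-m1)`` and the
uncertain process with ``1 - exp(-(f2 + m2))``; after extinction certain
sightings are impossible and uncertain sightings persist only at the
false-sighting background rate f2, with probability ``1 - exp(-f2)``.  Under
non-extinction the pre-extinction forms apply throughout the window.

Priors: tau uniform over the years from the last certain sighting to the
window end (inclusive); wide Uniform(0, 100) priors on m1, m2, f2; and a
non-informative Jeffreys Beta(0.5, 0.5) hyper-prior on the prior extinction
probability, whose expected value 0.5 is an evens bet of prior ignorance.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from ._mcmc import ModelKernel, PosteriorSummary, sample_posterior
from .records import ModelConfig, SightingRecord

_NEG_CLIP = -1e12  # finite stand-in for log(0): keeps 0 * log(0) = 0


__all__ = [
    "year_log_likelihood",
    "fit",
    "fit_with_fixed_prior",
    "PosteriorSummary",
]


def year_log_likelihood(
    year: int,
    s1_t: int,
    s2_t: int,
    m1: float,
    m2: float,
    f2: float,
    extinct: bool,
    tau: Optional[int] = None,
) -> float:
    """Log-likelihood contribution of one year's pair of sighting flags.

    A certain sighting after the extinction year is structurally impossible
    and returns ``-inf``.  The extinction year itself still uses the
    pre-extinction forms ("before or equal to the time of extinction").
    """
    if min(m1, m2, f2) < 0:
        raise ValueError("rates must be nonnegative")
    pre = (not extinct) or (tau is None) or (year <= tau)
    with np.errstate(divide="ignore"):
        if pre:
            lp1 = np.log(-np.expm1(-m1)) if s1_t else -m1
            lp2 = np.log(-np.expm1(-(f2 + m2))) if s2_t else -(f2 + m2)
        else:
            lp1 = -np.inf if s1_t else 0.0
            lp2 = np.log(-np.expm1(-f2)) if s2_t else -f2
    return float(lp1 + lp2)


# ---------------------------------------------------------------------------
# Kernel construction
# ---------------------------------------------------------------------------


def _tau_support(record: SightingRecord) -> tuple[int, np.ndarray]:
    """Discrete tau support: years from the last certain sighting to the
    window end, both inclusive."""
    i_lc = record.last_certain_year - record.start_year
    return i_lc, np.arange(record.last_certain_year, record.end_year + 1)


def _tau_norm(record: SightingRecord, config: ModelConfig) -> float:
    """Normalisation of the uniform tau prior (see ModelConfig.tau_prior)."""
    if config.tau_prior == "support":
        return float(np.log(record.end_year - record.last_certain_year + 1))
    return float(np.log(record.n_years))


def _rate_init(record: SightingRecord, upper: float):
    """Overdispersed starting rates near crude empirical sighting frequencies."""
    n = record.n_years
    m1_hat = max(len(record.certain_years) / n, 0.02)
    m2_hat = max(len(record.uncertain_years) / n, 0.02)

    def init(rng: np.random.Generator, K: int) -> np.ndarray:
        x = np.empty((K, 3))
        x[:, 0] = m1_hat * rng.uniform(0.5, 2.0, K)
        x[:, 1] = m2_hat * rng.uniform(0.5, 2.0, K)
        x[:, 2] = 0.5 * m2_hat * rng.uniform(0.5, 2.0, K)
        return np.clip(x, 1e-4, upper - 1e-6)

    return init


def _uniform_rate_prior(x: np.ndarray) -> np.ndarray:
    return np.zeros(x.shape[0])  # flat within the reflected bounds


def tau_count_profile(record: SightingRecord):
    """Cumulative year-type counts along the tau support.

    The per-year Bernoulli likelihood takes only a handful of distinct
    values (year types: certain hit, uncertain hit, miss, pre/post regime),
    so log L(tau) is a linear combination of *counts* of year types on each
    side of tau.  Returns, for each support index j (tau = year j of the
    window): ``jj`` years at-or-before tau, ``c2`` uncertain-sighting years
    at-or-before tau, plus the totals (N, n1, n2).  All certain sightings
    are at or before the last certain year, hence at or before any tau.
    """
    N = record.n_years
    i_lc = record.last_certain_year - record.start_year
    s2 = record.s2
    jj = np.arange(i_lc, N) + 1.0
    c2 = np.cumsum(s2)[i_lc:].astype(float)
    return jj, c2, float(N), float(len(record.certain_years)), float(s2.sum())


def base_kernel(record: SightingRecord, config: ModelConfig) -> ModelKernel:
    """The quality-ignoring model as a :class:`ModelKernel`.

    The likelihood over (E, tau) for every tau at once is a linear
    combination of cumulative year-type counts along the support.
    """
    record.validate()
    _, tau_years = _tau_support(record)
    jj, c2, N, n1, n2 = tau_count_profile(record)
    upper = config.rate_prior_upper

    def loglik(x: np.ndarray):
        m1 = x[:, 0:1]
        m2 = x[:, 1:2]
        f2 = x[:, 2:3]
        lp1 = np.clip(np.log(-np.expm1(-m1)), _NEG_CLIP, None)
        lp2_pre = np.clip(np.log(-np.expm1(-(f2 + m2))), _NEG_CLIP, None)
        lp2_post = np.clip(np.log(-np.expm1(-f2)), _NEG_CLIP, None)
        logL_notE = n1 * lp1 - (N - n1) * m1 + n2 * lp2_pre - (N - n2) * (f2 + m2)
        tau_ll = (
            n1 * lp1
            - (jj - n1) * m1
            + c2 * lp2_pre
            - (jj - c2) * (f2 + m2)
            + (n2 - c2) * lp2_post
            - ((N - jj) - (n2 - c2)) * f2
        )
        return logL_notE[:, 0], tau_ll

    return ModelKernel(
        names=["m1", "m2", "f2"],
        lower=np.zeros(3),
        upper=np.full(3, upper),
        logprior=_uniform_rate_prior,
        loglik=loglik,
        tau_years=tau_years,
        init=_rate_init(record, upper),
        model="base",
        log_tau_norm=_tau_norm(record, config),
    )


def _apply_fixed(kernel: ModelKernel, fixed: dict) -> ModelKernel:
    """Pin parameters named in ``fixed`` (used for reduction checks)."""
    if not fixed:
        return kernel
    for name, value in fixed.items():
        d = kernel.names.index(name)
        kernel.lower[d] = kernel.upper[d] = float(value)
    base_init = kernel.init

    def init(rng, K):
        x = base_init(rng, K)
        for name, value in fixed.items():
            x[:, kernel.names.index(name)] = float(value)
        return x

    kernel.init = init
    return kernel


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _run(kernel, config: ModelConfig, prior_weight: float, seed) -> PosteriorSummary:
    summary = sample_posterior(
        _apply_fixed(kernel, config.fixed_params),
        prior_weight=prior_weight,
        iterations=config.iterations,
        burn_in=config.burn_in,
        chains=config.chains,
        seed=config.seed if seed is None else seed,
        rhat_threshold=config.rhat_threshold,
        estimator=config.tau_estimator,
    )
    return summary


def fit(
    record: SightingRecord,
    config: Optional[ModelConfig] = None,
    seed: Optional[int] = None,
) -> PosteriorSummary:
    """Fit the base change-point model with the Jeffreys hyper-prior.

    The Beta(0.5, 0.5) hyper-prior on the prior extinction probability
    enters the extinction posterior only through its mean (0.5), because
    the binary extinct indicator is linear in its Bernoulli weight.
    """
    config = config or ModelConfig()
    return _run(base_kernel(record, config), config, config.hyperprior_mean, seed)


def fit_with_fixed_prior(
    record: SightingRecord,
    prior_pE: float,
    config: Optional[ModelConfig] = None,
    seed: Optional[int] = None,
) -> PosteriorSummary:
    """Fit with a fixed expert prior of extinction (prior-sensitivity runs)."""
    if not (0.0 < prior_pE < 1.0):
        raise ValueError("prior_pE must lie strictly in (0, 1); 0 and 1 are degenerate")
    config = config or ModelConfig()
    return _run(base_kernel(record, config), config, prior_pE, seed)
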