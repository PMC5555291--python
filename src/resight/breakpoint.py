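"""Quality-breakpoint model: a common change point in rates and quality.

If sighting quality collapses when a species goes extinct (all later
sightings being false), the quality series carries change-point information
of its own.  This model therefore optimises, jointly with the sighting-rate
change point, a Beta-distributed quality law that switches regime at the
same extinction year tau: uncertain-sighting qualities follow
Beta(alpha + alpha2, beta + beta2) before (or at) tau and the baseline
Beta(alpha, beta) afterwards.  The additive shape increments alpha2, beta2
(Exponential(1) priors, as for the baseline shapes) let the data decide how
different the two regimes are; alpha2 = beta2 = 0 recovers the sighting-only
model exactly.  Sightings and quality are modelled as independent processes,
so the joint likelihood is the product of the sighting likelihood and the
Beta quality terms, which enter only at uncertain-sighting years.

The quality block needs enough uncertain sightings on both sides of a
candidate change point to say anything; records without that depth (the
three bird records, with at most eight uncertain sightings) are refused
with :class:`InsufficientQualityData`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import betaln

from ._mcmc import ModelKernel, PosteriorSummary, sample_posterior
from .changepoint import _NEG_CLIP, _rate_init, _tau_norm, _tau_support, tau_count_profile
from .elicitation import QualitySeries
from .records import ModelConfig, QualityObservation, SightingRecord

__all__ = [
    "QualityRegime",
    "InsufficientQualityData",
    "joint_log_likelihood",
    "fit_breakpoint",
]

_EPS = 1e-6


class InsufficientQualityData(ValueError):
    """Too few uncertain sightings to seek a quality change point."""


@dataclass(frozen=True)
class QualityRegime:
    """Beta quality law with additive pre-extinction shape increments.

    Post-extinction quality ~ Beta(alpha, beta); pre-extinction quality
    ~ Beta(alpha + alpha2, beta + beta2).
    """

    alpha: float
    beta: float
    alpha2: float = 0.0
    beta2: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("baseline Beta shapes must be positive")
        if self.alpha2 < 0 or self.beta2 < 0:
            raise ValueError("shape increments must be nonnegative")

    @property
    def pre(self) -> tuple[float, float]:
        return (self.alpha + self.alpha2, self.beta + self.beta2)

    @property
    def post(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


def _quality_nodes(record, quality, quad_points):
    """Quadrature nodes/weights and year indices of uncertain sightings."""
    if isinstance(quality, QualitySeries):
        pairs = [
            (int(y), d)
            for y, d, p in zip(quality.years, quality.densities, quality.provenance)
            if p == "observed" and y in record.uncertain_years
        ]
    else:
        pairs = [
            (o.year, o.density()) for o in quality if o.year in record.uncertain_years
        ]
    pairs.sort(key=lambda p: p[0])
    if not pairs:
        raise InsufficientQualityData("record has no uncertain-sighting qualities")
    width = 0
    tables = []
    for y, d in pairs:
        x, w = d.nodes_weights(quad_points)
        tables.append((y - record.start_year, np.clip(x, _EPS, 1 - _EPS), w))
        width = max(width, len(x))
    idx = np.array([t[0] for t in tables])
    Q = np.zeros((len(tables), width))
    W = np.zeros((len(tables), width))
    for i, (_, x, w) in enumerate(tables):
        Q[i, : len(x)] = x
        W[i, : len(w)] = w
    return idx, Q, W


def _log_beta_term(Q, W, a, b):
    """log E_q[Beta(q; a, b)] per uncertain year, by quadrature.

    Shapes: Q, W are (n_unc, nodes); a, b are (K, 1); returns (K, n_unc).
    """
    lq = np.log(Q, where=W > 0, out=np.zeros_like(Q))
    l1q = np.log1p(-Q, where=W > 0, out=np.zeros_like(Q))
    logpdf = (
        (a[:, :, None] - 1) * lq[None, :, :]
        + (b[:, :, None] - 1) * l1q[None, :, :]
        - betaln(a, b)[:, :, None]
    )
    return np.log(np.einsum("nj,knj->kn", W, np.exp(logpdf)))


def joint_log_likelihood(
    state: dict,
    regime: QualityRegime,
    record: SightingRecord,
    quality: Union[Sequence[QualityObservation], QualitySeries],
    config: Optional[ModelConfig] = None,
) -> float:
    """Joint sighting + quality log-likelihood at one parameter point.

    ``state`` holds m1, m2, f2, extinct (bool) and tau (year).  Quality
    terms are Beta log-densities at uncertain-sighting years, marginalised
    over each observation's quality density; values at the support edges
    are clipped to [eps, 1-eps].  Mainly a reference implementation for
    validating the vectorised kernel.
    """
    config = config or ModelConfig()
    from .changepoint import year_log_likelihood

    m1, m2, f2 = state["m1"], state["m2"], state["f2"]
    extinct = bool(state.get("extinct", False))
    tau = state.get("tau")
    total = 0.0
    s1, s2 = record.s1, record.s2
    for i, year in enumerate(record.years):
        total += year_log_likelihood(year, int(s1[i]), int(s2[i]), m1, m2, f2, extinct, tau)
    idx, Q, W = _quality_nodes(record, quality, config.quad_points)
    a_pre, b_pre = regime.pre
    a_post, b_post = regime.post
    for i, t in enumerate(idx):
        year = record.start_year + t
        pre = (not extinct) or (tau is None) or (year <= tau)
        a, b = (a_pre, b_pre) if pre else (a_post, b_post)
        term = _log_beta_term(Q[i : i + 1], W[i : i + 1], np.array([[a]]), np.array([[b]]))
        total += float(term[0, 0])
    return total


def _check_depth(record: SightingRecord, config: ModelConfig) -> None:
    """Refuse records without enough uncertain sightings for two regimes.

    Requires (i) at least ``min_uncertain_breakpoint`` uncertain sightings
    in total — two Beta regimes mean four shape parameters to learn — and
    (ii) some candidate tau in the support with at least three uncertain
    sightings on each side.
    """
    unc = np.sort([y for y in record.uncertain_years])
    n = len(unc)
    msg = None
    if n < config.min_uncertain_breakpoint:
        msg = (
            f"only {n} uncertain sightings; seeking a quality change point needs "
            f">= {config.min_uncertain_breakpoint}"
        )
    else:
        lc, end = record.last_certain_year, record.end_year
        ok = any(
            (unc <= tau).sum() >= 3 and (unc > tau).sum() >= 3 for tau in range(lc, end + 1)
        )
        if not ok:
            msg = (
                "no candidate extinction year splits the uncertain sightings "
                "3-and-3; the quality regimes are unidentifiable"
            )
    if msg:
        raise InsufficientQualityData(
            f"not enough uncertain sightings to seek a change point: {msg}"
        )


def breakpoint_kernel(
    record: SightingRecord,
    quality: Union[Sequence[QualityObservation], QualitySeries],
    config: ModelConfig,
) -> ModelKernel:
    record.validate()
    _, tau_years = _tau_support(record)
    jj, c2, N, n1, n2 = tau_count_profile(record)
    upper = config.rate_prior_upper
    idx, Q, W = _quality_nodes(record, quality, config.quad_points)
    i_lc = record.last_certain_year - record.start_year
    # cumulative count of uncertain sightings at-or-before each support tau
    # maps each uncertain sighting to pre/post regime per tau
    pre_mask = idx[None, :] <= np.arange(i_lc, record.n_years)[:, None]  # (ntau, n_unc)

    def logprior(x):
        # flat on rates; Exponential(1) on the four Beta shape parameters
        return -x[:, 3:].sum(axis=1)

    def loglik(x):
        m1 = x[:, 0:1]
        m2 = x[:, 1:2]
        f2 = x[:, 2:3]
        alpha = x[:, 3:4]
        beta = x[:, 4:5]
        alpha2 = x[:, 5:6]
        beta2 = x[:, 6:7]
        lp1 = np.clip(np.log(-np.expm1(-m1)), _NEG_CLIP, None)
        lp2_pre = np.clip(np.log(-np.expm1(-(f2 + m2))), _NEG_CLIP, None)
        lp2_post = np.clip(np.log(-np.expm1(-f2)), _NEG_CLIP, None)
        s_notE = n1 * lp1 - (N - n1) * m1 + n2 * lp2_pre - (N - n2) * (f2 + m2)
        s_tau = (
            n1 * lp1
            - (jj - n1) * m1
            + c2 * lp2_pre
            - (jj - c2) * (f2 + m2)
            + (n2 - c2) * lp2_post
            - ((N - jj) - (n2 - c2)) * f2
        )
        q_pre = _log_beta_term(Q, W, alpha + alpha2, beta + beta2)  # (K, n_unc)
        q_post = _log_beta_term(Q, W, alpha, beta)
        q_notE = q_pre.sum(axis=1)
        # per tau: pre-regime terms for sightings at-or-before tau, post after
        q_tau = q_pre @ pre_mask.T + q_post @ (~pre_mask).T  # (K, ntau)
        return s_notE[:, 0] + q_notE, s_tau + q_tau

    def init(rng, K):
        x = np.empty((K, 7))
        x[:, :3] = _rate_init(record, upper)(rng, K)
        x[:, 3:] = rng.uniform(0.5, 2.0, (K, 4))
        return x

    return ModelKernel(
        names=["m1", "m2", "f2", "alpha", "beta", "alpha2", "beta2"],
        lower=np.zeros(7),
        upper=np.array([upper, upper, upper, np.inf, np.inf, np.inf, np.inf]),
        logprior=logprior,
        loglik=loglik,
        tau_years=tau_years,
        init=init,
        model="breakpoint",
        log_tau_norm=_tau_norm(record, config),
    )


def fit_breakpoint(
    record: SightingRecord,
    quality: Union[Sequence[QualityObservation], QualitySeries],
    config: Optional[ModelConfig] = None,
    seed: Optional[int] = None,
) -> PosteriorSummary:
    """Fit the joint rate + quality change-point model.

    Raises :class:`InsufficientQualityData` when the record lacks the
    uncertain-sighting depth to identify two quality regimes (see
    ``ModelConfig.min_uncertain_breakpoint``).
    """
    config = config or ModelConfig()
    _check_depth(record, config)
    kernel = breakpoint_kernel(record, quality, config)
    from .changepoint import _apply_fixed

    return sample_posterior(
        _apply_fixed(kernel, config.fixed_params),
        prior_weight=config.hyperprior_mean,
        iterations=config.iterations,
        burn_in=config.burn_in,
        chains=config.chains,
        seed=config.seed if seed is None else seed,
        rhat_threshold=config.rhat_threshold,
        estimator=config.tau_estimator,
    )
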