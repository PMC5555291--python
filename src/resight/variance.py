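"""Quality-as-variance model: quality inflates uncertain-sighting variance.

Low-quality uncertain sightings should count for less.  Here the true
uncertain-sighting rate m2 at year t is multiplied by a unit-mean Gamma
"fuzz" r ~ Gamma(1/H_t, 1/H_t) with variance H_t = -a ln(q_t), a log-link
between quality and uncertainty: q = 1 gives no fuzz, q -> 0 unbounded fuzz,
and the penalty a scales how harshly low quality is punished (a = 0 recovers
the base model exactly).  The fuzz applies only to m2 — the false-sighting
offset f2 is a fixed background property of the record and is never fuzzed.

Per-year multipliers are independent, so the likelihood marginalises them in
closed form through the Gamma moment generating function:

    E_r[exp(-m2 r)] = (1 + m2 H_t)^(-1/H_t)

giving P(no uncertain sighting) = exp(-f2) (1 + m2 H_t)^(-1/H_t) before
extinction.  Quality ranges and imputed years are likewise integrated over
their quality densities by quadrature, so the fit is deterministic given the
sampler seed.
"""
from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from ._mcmc import ModelKernel, PosteriorSummary, sample_posterior
from .changepoint import (
    _NEG_CLIP,
    _rate_init,
    _tau_norm,
    _tau_support,
    _uniform_rate_prior,
    base_kernel,
)
from .elicitation import QualitySeries, impute_series
from .records import ModelConfig, QualityObservation, SightingRecord

__all__ = [
    "fuzz_magnitude",
    "sample_multiplier",
    "fit_variance",
    "assign_random_quality",
]

_EPS = 1e-6


def fuzz_magnitude(q_t: float, a: float) -> float:
    """Fuzz magnitude H = -a ln(q): the variance of the rate multiplier.

    Zero when the sighting is certain (q = 1) or quality is ignored (a = 0);
    grows without bound as quality falls to zero.
    """
    if a < 0:
        raise ValueError("penalty a must be nonnegative")
    q = np.asarray(q_t, dtype=float)
    if np.any(q <= 0):
        raise ValueError("quality must be strictly positive (log of 0 undefined)")
    if np.any(q > 1):
        raise ValueError("quality must not exceed 1")
    out = -a * np.log(q)
    return float(out) if np.isscalar(q_t) else out


def sample_multiplier(H_t: float, seed=None, size=None) -> Union[float, np.ndarray]:
    """Draw the unit-mean Gamma rate multiplier r ~ Gamma(1/H, rate 1/H).

    E[r] = 1 for every H (fuzz never biases the rate, only spreads it) and
    Var[r] = H.  H = 0 is the degenerate no-fuzz limit, r = 1 exactly.
    """
    if H_t < 0:
        raise ValueError("fuzz magnitude H must be nonnegative")
    if H_t == 0:
        return 1.0 if size is None else np.ones(size)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = 1.0 / H_t
    return rng.gamma(shape=k, scale=H_t, size=size)


def _log_mgf_term(m2: np.ndarray, H: np.ndarray) -> np.ndarray:
    """log E_r[exp(-m2 r)] = -(1/H) log(1 + m2 H), with the H->0 limit -m2."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(H > 0, -np.log1p(m2 * H) / np.where(H > 0, H, 1.0), -m2)
    return out


def _series_from(record, quality, config, seed) -> QualitySeries:
    if isinstance(quality, QualitySeries):
        return quality
    obs = list(quality)
    if config.range_handling == "midpoint":
        obs = [
            QualityObservation(o.year, "point", 0.5 * (o.value[0] + o.value[1]))
            if o.kind == "range"
            else o
            for o in obs
        ]
    return impute_series(record, obs, seed=seed)


def variance_kernel(
    record: SightingRecord,
    series: QualitySeries,
    config: ModelConfig,
) -> ModelKernel:
    """Marginal likelihood kernel of the quality-as-variance model.

    Every window year carries a quality law (observed, imputed by LOCF/FOCB,
    or q = 1 at certain years); the per-year Gamma multiplier and the
    quality value are both integrated out, the latter by quadrature over
    each year's density.  Years inheriting the same sighting's density share
    one quadrature, so the cost scales with the number of distinct laws.
    """
    record.validate()
    a = config.penalty_a
    s2 = record.s2
    N = record.n_years
    i_lc, tau_years = _tau_support(record)
    upper = config.rate_prior_upper
    from .changepoint import tau_count_profile

    jj, c2, Nf, n1, n2 = tau_count_profile(record)

    # Quadrature tables (H at each density's nodes) and cumulative counts of
    # zero/hit years per density group along the tau support.
    Hs, Ws, C0, CU, tot0, totU = [], [], [], [], [], []
    for density, idx in series.density_groups():
        nodes, weights = density.nodes_weights(config.quad_points)
        Hs.append(-a * np.log(np.clip(nodes, _EPS, 1.0)))
        Ws.append(weights)
        member = np.zeros(N)
        member[idx] = 1.0
        C0.append(np.cumsum(member * (1 - s2))[i_lc:])
        CU.append(np.cumsum(member * s2)[i_lc:])
        tot0.append(float((member * (1 - s2)).sum()))
        totU.append(float((member * s2).sum()))
    C0, CU = np.array(C0), np.array(CU)
    tot0, totU = np.array(tot0), np.array(totU)
    # pad per-group quadrature tables to one (G, nodes) pair so the Gamma
    # MGF term is evaluated in a single vectorised pass
    width = max(len(h) for h in Hs)
    Hmat = np.zeros((len(Hs), width))
    Wmat = np.zeros((len(Ws), width))
    for g, (h, w) in enumerate(zip(Hs, Ws)):
        Hmat[g, : len(h)] = h
        Wmat[g, : len(w)] = w

    def loglik(x: np.ndarray):
        m1 = x[:, 0:1]
        m2 = x[:, 1:2]
        f2 = x[:, 2:3]
        lp1 = np.clip(np.log(-np.expm1(-m1)), _NEG_CLIP, None)
        lp2_post = np.clip(np.log(-np.expm1(-f2)), _NEG_CLIP, None)
        # per group: log E_q E_r[exp(-m2 r)] and log P(hit | pre-extinction)
        term = np.exp(_log_mgf_term(m2[:, :, None], Hmat[None, :, :]))  # (K, G, nodes)
        logG = np.log((Wmat[None, :, :] * term).sum(axis=2))  # (K, G)
        pre_hit = np.clip(np.log1p(-np.exp(logG - f2)), _NEG_CLIP, None)  # (K, G)
        logL_notE = (
            n1 * lp1[:, 0]
            - (Nf - n1) * m1[:, 0]
            + logG @ tot0
            - f2[:, 0] * (Nf - n2)
            + pre_hit @ totU
        )
        tau_ll = (
            n1 * lp1
            - (jj - n1) * m1
            + logG @ C0
            - (jj - c2) * f2
            + pre_hit @ CU
            + (n2 - c2) * lp2_post
            - ((Nf - jj) - (n2 - c2)) * f2
        )
        return logL_notE, tau_ll

    return ModelKernel(
        names=["m1", "m2", "f2"],
        lower=np.zeros(3),
        upper=np.full(3, upper),
        logprior=_uniform_rate_prior,
        loglik=loglik,
        tau_years=tau_years,
        init=_rate_init(record, upper),
        model="variance",
        log_tau_norm=_tau_norm(record, config),
    )


def fit_variance(
    record: SightingRecord,
    quality: Union[Sequence[QualityObservation], QualitySeries],
    config: Optional[ModelConfig] = None,
    seed: Optional[int] = None,
) -> PosteriorSummary:
    """Fit the quality-as-variance model (Jeffreys hyper-prior).

    ``quality`` is either raw per-sighting observations (a full series is
    then imputed by randomised LOCF/FOCB) or a prebuilt
    :class:`QualitySeries`.  A record with no uncertain sightings in the
    window has nothing to fuzz and is fitted with the base likelihood,
    which is the exact q = 1 limit of this model.
    """
    config = config or ModelConfig()
    flags = []
    if not record.uncertain_years:
        kernel = base_kernel(record, config)
        kernel.model = "variance"
        flags.append("no_uncertain_sightings_base_likelihood")
        series = None
    else:
        quality = _check_uncertain_quality(record, quality)
        series = _series_from(record, quality, config, seed)
        kernel = variance_kernel(record, series, config)
    summary = sample_posterior(
        kernel,
        prior_weight=config.hyperprior_mean,
        iterations=config.iterations,
        burn_in=config.burn_in,
        chains=config.chains,
        seed=config.seed if seed is None else seed,
        rhat_threshold=config.rhat_threshold,
        estimator=config.tau_estimator,
        extra_flags=flags,
    )
    return summary


def _check_uncertain_quality(record, quality):
    """Warn-and-coerce q=1 claims on uncertain years (H=0, no fuzz)."""
    if isinstance(quality, QualitySeries):
        return quality
    import warnings

    out = []
    for o in quality:
        if o.kind == "point" and o.year in record.uncertain_years and float(o.value) >= 1.0:
            warnings.warn(
                f"year {o.year}: q=1 claimed on an uncertain sighting; treated as "
                "H=0 (no fuzz)",
                stacklevel=3,
            )
            out.append(QualityObservation(o.year, "point", 1.0 - _EPS))
        else:
            out.append(o)
    return out


def assign_random_quality(
    record: SightingRecord,
    seed: Optional[int] = None,
    eps: float = _EPS,
) -> list[QualityObservation]:
    """Replace expert quality with random Uniform(eps, 1-eps) scores.

    Used to test whether expert scores carry signal: if random scores give
    similar extinction inferences, the expert elicitation is superfluous.
    """
    if not record.uncertain_years:
        raise ValueError("record has no uncertain sightings to score")
    rng = np.random.default_rng(seed)
    return [
        QualityObservation(int(y), "point", float(rng.uniform(eps, 1 - eps)))
        for y in sorted(record.uncertain_years)
    ]
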