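"""Independent brute-force oracles used to validate the samplers.

Everything here is written directly from the model definition (per-year
Bernoulli likelihoods, uniform priors, discrete extinction year) with plain
grid enumeration — deliberately sharing no code with the package kernels.
"""
from __future__ import annotations

import numpy as np


def enumerate_p_extinct(
    record,
    rate_upper: float,
    n_grid: int = 40,
    prior_weight: float = 0.5,
    tau_prior: str = "window",
    fixed=None,
):
    """Posterior extinction probability by midpoint-rule enumeration.

    Integrates the per-year Bernoulli likelihood over a cubic midpoint grid
    on the Uniform(0, rate_upper)^3 rate prior, summing the discrete
    extinction year over [last certain sighting, window end] and weighting
    the extinct branch by ``prior_weight``.  Also returns the posterior of
    the extinction year given extinction.
    """
    fixed = fixed or {}
    years = record.years
    s1 = record.s1.astype(float)
    s2 = record.s2.astype(float)
    N = len(years)
    i_lc = int(record.last_certain_year - record.start_year)
    tau_idx = np.arange(i_lc, N)

    def axis(name):
        if name in fixed:
            return np.array([float(fixed[name])])
        h = rate_upper / n_grid
        return np.linspace(h / 2, rate_upper - h / 2, n_grid)

    m1g, m2g, f2g = np.meshgrid(axis("m1"), axis("m2"), axis("f2"), indexing="ij")
    m1 = m1g.ravel()[:, None]
    m2 = m2g.ravel()[:, None]
    f2 = f2g.ravel()[:, None]

    with np.errstate(divide="ignore"):
        lp1_hit = np.log1p(-np.exp(-m1))
        lp2_hit_pre = np.log1p(-np.exp(-(f2 + m2)))
        lp2_hit_post = np.log1p(-np.exp(-f2))
        # per-year log-probabilities, shape (grid, N); where() avoids 0*log(0)
        A = (
            np.where(s1 > 0, lp1_hit, -m1)
            + np.where(s2 > 0, lp2_hit_pre, -(f2 + m2))
        )
        B = np.where(s2 > 0, lp2_hit_post, -f2)

    cumA = np.cumsum(A, axis=1)
    # suffix sums of B strictly after each tau
    revB = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    suffB = np.concatenate([revB, np.zeros((B.shape[0], 1))], axis=1)
    log_tau = cumA[:, tau_idx] + suffB[:, tau_idx + 1]
    norm = N if tau_prior == "window" else len(tau_idx)

    L_notE = np.exp(cumA[:, -1])
    L_tau = np.exp(log_tau)
    L_E = L_tau.sum(axis=1) / norm

    w = prior_weight
    num = w * L_E.mean()
    den = num + (1 - w) * L_notE.mean()
    p_extinct = num / den
    tau_post = (w * L_tau).mean(axis=0)
    tau_post = tau_post / tau_post.sum()
    return p_extinct, years[tau_idx], tau_post
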