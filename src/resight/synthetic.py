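"""Synthetic sighting records, qualities and elicitations.

Generates data with exactly the statistical structure the models assume —
parallel per-year Bernoulli certain/uncertain sighting processes with a
false-sighting background that persists after the extinction year, plus
per-sighting quality laws and noisy multi-expert triangle elicitations —
so that parameter recovery, regime detection and pooling can all be tested
without any external record.  Lion-like records (interlaced certain and
uncertain annual sightings with per-sighting quality densities over a
~60-year window) are the main template, since that record's sighting years
are not available in public tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .densities import BetaQuality
from .elicitation import TriangleElicitation
from .records import QualityObservation, SightingRecord

__all__ = ["SimulationSpec", "simulate_record", "simulate_quality", "simulate_elicitation"]

_MAX_RETRIES = 100


@dataclass
class SimulationSpec:
    """Generative settings for one synthetic record.

    Default rates follow a lion-like sparse record over a 60-year window:
    certain sightings at m1 = 0.3/yr, true uncertain sightings at
    m2 = 0.2/yr over a false-sighting background f2 = 0.05/yr, extinction
    at mid-window.  Quality regimes: "expert_like" draws sighting qualities
    from distinct pre/post-extinction Beta laws (informative quality, high
    before extinction and low after by default), "random_uniform" from
    Uniform(eps, 1-eps) (no signal), "ranged" additionally widens each
    drawn quality into a published-style (lo, hi) interval.
    """

    T: int = 60
    tau_E: Optional[int] = 30  # years after window start; None = extant
    m1: float = 0.3
    m2: float = 0.2
    f2: float = 0.05
    start_year: int = 1900
    quality_regime: str = "expert_like"  # | "random_uniform" | "ranged"
    pre_beta: tuple[float, float] = (8.0, 2.0)
    post_beta: tuple[float, float] = (2.0, 8.0)
    range_halfwidth: float = 0.15
    n_experts: int = 5
    n_questions: int = 3
    triangle_noise: float = 0.1
    seed: Optional[int] = None
    rate_prior_upper: float = 100.0

    def __post_init__(self):
        for name in ("m1", "m2", "f2"):
            v = getattr(self, name)
            if not (0.0 <= v <= self.rate_prior_upper):
                raise ValueError(f"{name}={v} outside [0, {self.rate_prior_upper}]")
        if self.tau_E is not None and not (0 <= self.tau_E <= self.T):
            raise ValueError("tau_E must lie within the window")
        if min(*self.pre_beta, *self.post_beta) <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def tau_year(self) -> Optional[int]:
        return None if self.tau_E is None else self.start_year + self.tau_E


def simulate_record(spec: SimulationSpec, rng: Optional[np.random.Generator] = None) -> SightingRecord:
    """Draw one sighting record from the model's generative process.

    Per year t: a certain sighting with probability ``1 - exp(-m1)`` up to
    the extinction year (inclusive) and never afterwards; an uncertain
    sighting with probability ``1 - exp(-(f2 + m2))`` up to extinction and
    ``1 - exp(-f2)`` afterwards.  The first window year is forced to carry
    a certain sighting (the record's anchor); draws are repeated until the
    record has at least two certain sightings, erroring after bounded
    retries so impossible specs fail loudly rather than spinning.
    """
    rng = rng or np.random.default_rng(spec.seed)
    N = spec.T + 1
    tau = spec.tau_E if spec.tau_E is not None else spec.T
    p1 = -np.expm1(-spec.m1)
    p2_pre = -np.expm1(-(spec.f2 + spec.m2))
    p2_post = -np.expm1(-spec.f2)
    for _ in range(_MAX_RETRIES):
        t = np.arange(N)
        pre = t <= tau
        s1 = (rng.random(N) < np.where(pre, p1, 0.0)).astype(int)
        s1[0] = 1  # anchor
        s2 = (rng.random(N) < np.where(pre, p2_pre, p2_post)).astype(int)
        if s1.sum() >= 2:
            years = spec.start_year + t
            return SightingRecord(
                frozenset(years[s1 == 1].tolist()),
                frozenset(years[s2 == 1].tolist()),
                (spec.start_year, spec.start_year + spec.T),
            )
    raise RuntimeError(
        f"could not draw >= 2 certain sightings in {_MAX_RETRIES} tries; "
        f"increase m1 (= {spec.m1}) or T"
    )


def simulate_quality(
    record: SightingRecord,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> list[QualityObservation]:
    """Draw per-uncertain-sighting qualities under the spec's regime."""
    if not record.uncertain_years:
        raise ValueError("record has no uncertain sightings to score")
    rng = rng or np.random.default_rng(spec.seed)
    eps = 1e-3
    tau_year = spec.tau_year if spec.tau_year is not None else record.end_year
    pre_law = BetaQuality(*spec.pre_beta)
    post_law = BetaQuality(*spec.post_beta)
    out = []
    for y in sorted(record.uncertain_years):
        if spec.quality_regime == "random_uniform":
            q = rng.uniform(eps, 1 - eps)
        else:
            law = pre_law if y <= tau_year else post_law
            q = float(np.clip(law.rvs(rng), eps, 1 - eps))
        if spec.quality_regime == "ranged":
            lo = max(0.0, q - spec.range_halfwidth)
            hi = min(1.0, q + spec.range_halfwidth)
            out.append(QualityObservation(int(y), "range", (round(lo, 2), round(hi, 2))))
        else:
            out.append(QualityObservation(int(y), "point", q))
    return out


def simulate_elicitation(
    q_true: float,
    spec: Optional[SimulationSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[TriangleElicitation]:
    """Simulate a multi-expert, multi-question triangle elicitation.

    Each expert answers each question with a best estimate centred on the
    true quality (Gaussian noise, sd ``triangle_noise``) and lower/upper
    bounds placed below/above it; with the defaults this yields the usual
    5 experts x 3 questions = 15 triangles to pool.
    """
    if not (0.0 < q_true < 1.0):
        raise ValueError("q_true must lie strictly in (0, 1)")
    spec = spec or SimulationSpec()
    rng = rng or np.random.default_rng(spec.seed)
    sd = spec.triangle_noise
    out = []
    for e in range(spec.n_experts):
        for j in range(spec.n_questions):
            best = float(np.clip(q_true + rng.normal(0.0, sd), 0.0, 1.0))
            lower = float(np.clip(best - np.abs(rng.normal(0.0, sd)) - 0.01, 0.0, best))
            upper = float(np.clip(best + np.abs(rng.normal(0.0, sd)) + 0.01, best, 1.0))
            out.append(
                TriangleElicitation(lower, best, upper, f"expert_{e + 1}", f"question_{j + 1}")
            )
    return out
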