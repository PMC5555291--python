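# Methods

## Model and inference

All three models share one latent structure: a binary extinct indicator E,
a discrete extinction year τ, and a small continuous block (sighting rates
m₁, m₂, f₂; plus four Beta shape parameters in the breakpoint model).
Conditional on the continuous block the likelihood factorises over years,
so E and τ are summed out exactly at every sampler iteration: the
Metropolis-within-Gibbs random walk (component-wise Gaussian proposals
reflected at the prior bounds, per-chain step sizes adapted toward 35%
acceptance during burn-in and frozen after) only explores the 3–7
continuous dimensions.  This Rao-Blackwellisation leaves the posterior
unchanged while making the reported extinction probability an average of
smooth conditional probabilities rather than a binary trace, which cuts its
Monte-Carlo error dramatically — important because the sequential runner's
"overwhelm year" compares that probability against a threshold.

Because the per-year Bernoulli likelihood takes only a handful of distinct
values (certain hit/miss, uncertain hit/miss, pre/post regime), the
log-likelihood profile over every candidate τ is a linear combination of
cumulative year-type counts, precomputed once per record.  One likelihood
evaluation costs a few small vector operations regardless of how the window
grows, and the four chains advance in lock-step as matrix rows.

The Beta(0.5, 0.5) hyper-prior on the prior extinction probability p(E)
enters the marginal posterior of E only through its expectation: E is
Bernoulli(pE) and a priori independent of everything else, so integrating
pE out replaces it by its mean, 0.5.  The hyper-prior run is therefore
computed exactly with prior weight 0.5; `fit_with_fixed_prior` substitutes
any fixed expert prior.  The posterior standard deviation reported for the
binary indicator is √(p(1−p)), which is what a binary MCMC trace converges
to.

Latent-variable integrals in the quality-as-variance model are taken in
closed form: per-year unit-mean Gamma multipliers have
E[e^(−m₂r)] = (1 + m₂Hₜ)^(−1/Hₜ) (the Gamma moment generating function),
and quality values (ranges, triangle pools, imputed years) are integrated
over their densities by Gauss–Legendre quadrature between density
breakpoints (16 nodes by default; years inheriting the same sighting's
density share one quadrature).  The original formulation samples these
latents; marginalising them yields the identical posterior with a
deterministic likelihood.  `sample_multiplier` exposes the generative draw,
and the tests verify the conservation law E[m₂′] = m₂ and Var[r] = H by
Monte Carlo.

Convergence is monitored with split-R̂ and bulk ESS (arviz) on every
sampled scalar plus the conditional extinction probability; R̂ > 1.05 flags
`not_converged` on the summary rather than raising.  Defaults: 4 chains,
10 000 iterations, 2 000 burn-in.

## Conventions that the data do not pin down

**τ prior normalisation.** τ is uniform "from the last certain sighting to
the end of the record", but the marginal likelihood of the extinct branch
depends on whether that uniform is normalised over the τ-support alone or
over the whole window (years before the last certain sighting have zero
likelihood and only dilute the branch).  The two readings give materially
different extinction probabilities early in a sequential sweep; only the
whole-window reading reproduces the published bird trajectories (e.g. the
grebe's 1998 overwhelm year — the support reading crosses 0.5 already in
the mid-1970s).  Default `tau_prior="window"`, with `"support"` available.

**Extinction-year summary.** The τ posterior given extinction is summarised
by its mode (ties to the earlier year); mean and median are also reported.
The mode matches the published full-record years and their
cluster-jumping behaviour (an estimate can move from ~1973 to 1988 as two
posterior clusters trade mass, which a mean cannot do), at the cost that a
heavily right-skewed posterior — the petrel's, whose likelihood peaks at
the final 1891 sighting and decays slowly — is summarised at its peak
(1891) where a mean-type summary would sit ~12 years later.

**Window anchor.** The likelihood requires a certain sighting in the first
window year.  Records whose first sighting is unverified (the petrel's
1789 report) follow the standard anchoring assumption that the
record-opening sighting is certain, as is done for the lion's 1895 record
in this literature.  `read_record` instead drops leading uncertain rows
with a warning, since arbitrary CSVs carry no such convention.

**The τ-year itself is pre-extinction** ("before or equal"), support
inclusive at both ends.  τ = T (extinct in the final year) is
observationally identical to extant.

**Quality at a knife-edge.** q = 1 claimed on an uncertain sighting is
treated as H = 0 with a warning; quality values at the support edges are
clipped to [10⁻⁶, 1−10⁻⁶] where logs or Beta densities are evaluated.
Quality ranges enter the likelihood integrated over Uniform(lo, hi) by
default (`range_handling="midpoint"` fixes the midpoint instead).

**Breakpoint identifiability.** The pre-extinction quality law is
Beta(α+α₂, β+β₂) with α₂, β₂ ≥ 0 free parameters under Exponential(1)
priors (as for α, β) — additive increments encode a soft regime contrast
while nesting the sighting-only model at α₂ = β₂ = 0.  Fitting requires at
least 10 uncertain sightings in total (four shape parameters to learn) and
a candidate τ with three uncertain sightings on each side; the three bird
records fail this and are refused with an explanatory error.  A "≥3 per
side" rule alone would admit the grebe (8 uncertain sightings split 4/4),
which the published treatment of the birds contradicts; the total-count
floor is this package's quantification of that refusal.

**Records with nothing to fuzz.** A (possibly truncated) record with no
uncertain sightings is fitted by the variance model with the base
likelihood — the exact q ≡ 1 limit — and flagged, so sequential sweeps that
begin before the first unverified report (the starling's 1996–2007 years)
proceed.

## Sequential runner

Years run from the one after the last certain sighting to the window end
(2016 for the shipped records).  Each yearly fit is independent, with its
own seed derived deterministically from (master seed, year), so the final
year's fit is bit-identical to a direct full-record fit under the same
policy.  The overwhelm year is the first with posterior extinction
probability strictly above the prior's expected value (0.5 under the
hyper-prior; the fixed prior itself in sensitivity runs).  Near the
threshold this comparison is genuinely knife-edged: for the grebe the
posterior at 1997 is 0.500 ± 0.003 under both base and variance models, so
the detected year can move by one with the seed — the published panels show
the same indeterminacy (extinction year 1973 in one panel, 1974 in two
others, at the same overwhelm year).

## Synthetic data

`SimulationSpec` defaults describe a sparse lion-like record: T = 60 years,
extinction at mid-window, m₁ = 0.3, m₂ = 0.2, f₂ = 0.05, with per-sighting
qualities drawn Beta(8, 2) before extinction and Beta(2, 8) after
("expert_like"), Uniform ("random_uniform"), or widened into published-style
ranges ("ranged"); elicitations are 5 experts × 3 questions of noisy
triangles around the true quality.  The generator reproduces exactly the
structure the models assume — stationary rates, a single change point, a
constant false-sighting background, quality independent of sighting
occurrence.  Passing tests therefore demonstrate internal consistency and
parameter recovery, not robustness to what real records add: publicity
bursts, observer-effort trends, correlated expert error, or quality that
drifts for human reasons (cameras, living witnesses) unrelated to
extinction — the last being precisely the failure mode that motivates
preferring certain/uncertain flags over fine-grained expert scores.
Anchoring is by retry (≤100 redraws until ≥2 certain sightings), so very
small m₁·T specs fail loudly.

Tests compare the samplers against an independent brute-force enumeration
(midpoint-rule integration over the rate cube × exhaustive τ sum) on
20-year records with the rate prior bounded at 2, where the grid resolves
the posterior; agreement is required to 0.02 in extinction probability.
Property sizes (50-record coverage runs, 20-record quality-superfluity
comparisons, 10-record nested reductions) keep the full suite to minutes
while leaving binomial noise well inside the asserted margins.

## Known limitations

- No population-decline dynamics: rates are constant until extinction.
- One class of uncertain sightings; no multi-class quality tiers.
- Sighting occurrence and quality are independent by assumption; the
  variance method relaxes this only through the per-year fuzz.
- The false-sighting background f₂ is constant for the whole record and is
  never fuzzed by quality.
- Post-extinction quality is not modelled as decaying; the breakpoint
  model's two Beta regimes are the only quality dynamics.
- Calendar-year discretisation throughout; sub-annual information is lost.
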