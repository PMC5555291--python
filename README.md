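# resight

Bayesian inference of extinction from sighting records that mix *certain*
(verified) and *uncertain* (unverified) observations, with two extensions
that exploit per-sighting **quality** scores, diagnostics for expert-elicited
quality, a sequential "data as it stands each year" runner, and a synthetic
record generator.  Intended for conservation scientists asking the question
behind IUCN "possibly extinct" listings: given a trickle of unverified
reports after the last confirmed record, how probable is it that the species
is gone, and when did it go?

## The model

Over an observation window (0, T), certain and uncertain sightings are
parallel stationary Poisson processes discretised to per-year Bernoulli
flags.  With extinction at year τ:

- certain sightings: P(s₁ₜ = 1) = 1 − e^(−m₁) for t ≤ τ, impossible after;
- uncertain sightings: P(s₂ₜ = 1) = 1 − e^(−(f₂+m₂)) for t ≤ τ, and
  1 − e^(−f₂) after, where f₂ is a constant false-sighting background.

The posterior follows Bayes' rule over the extinct/extant indicator E, with
a non-informative Jeffreys Beta(0.5, 0.5) hyper-prior on the prior
extinction probability (expected value 0.5 — an evens bet), τ uniform over
the window years at or after the last certain sighting, and wide
Uniform(0, 100) priors on m₁, m₂, f₂.

Two ways to use per-sighting quality q ∈ [0, 1) of uncertain sightings
(q = 1 denotes certainty):

- **quality breakpoint**: qualities follow Beta(α+α₂, β+β₂) before τ and
  Beta(α, β) after, fitted jointly with the sighting rates so both signals
  must agree on a common change point;
- **quality as variance**: each year's true uncertain rate is fuzzed,
  m₂′ = m₂·r with r ~ Gamma(1/Hₜ, 1/Hₜ), E[r] = 1, Var[r] = Hₜ = −a·ln(qₜ):
  low quality inflates variance without biasing the rate.  The penalty `a`
  (typical choices 1, 2, 4) scales the punishment; a = 0 recovers the
  base model.

Missing quality values are imputed by randomised last-observation-carried-
forward / first-observation-carried-backward: each unobserved year draws
from the nearest sighting's quality density.  Expert judgements arrive as
(lower, best, upper) triangle densities pooled linearly across experts and
questions; before/after t-test sweeps and a quality-only Bayes factor probe
whether the quality process itself shifted regime.

## Worked example

Three published bird sighting records ship with the package.  The Alaotra
grebe (last certain sighting 1969, unverified reports to 1988):

```python
from resight import ModelConfig, run_sequential
from resight.datasets import load_bird

record, quality = load_bird("alaotra_grebe")
traj = run_sequential(record, model="variance", quality=quality,
                      config=ModelConfig(penalty_a=2.0), seed=1)
print(traj.overwhelm_year, traj.overwhelm_summary.extinction_year)
print(traj.final_extinction_year, round(traj.final_summary.p_extinct, 2))
```

prints

```
1998 1972
1988 0.89
```

Reading: refitting on the data as it stood each year, the posterior
probability of extinction first exceeds the prior's expected value (0.5) in
1998 — only then do the data overwhelm prior ignorance — and the fit at that
point dates extinction to about 1972, just after the last cluster of
unverified reports.  With the full record to 2016 the extinction year
estimate is 1988 (the final unverified report), with posterior extinction
probability 0.89.  The same runner on the Pohnpei starling never crosses
0.5: two certain sightings and one unverified report are simply not enough
data.

The same operations are available from a shell:

```
resight fit --record grebe.csv --quality-mode variance --penalty-a 2 --seed 1
resight sequential --record grebe.csv --model variance --end-year 2016 --out traj.csv
resight simulate --spec spec.yaml --seed 7 --out record.csv
```

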