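"""Base change-point model: per-year likelihood, MCMC vs enumeration,
prior sensitivity and parameter recovery."""
import numpy as np
import pytest

from resight import (
    ModelConfig,
    SightingRecord,
    fit,
    fit_with_fixed_prior,
    year_log_likelihood,
)
from resight.synthetic import SimulationSpec, simulate_record

from _oracle import enumerate_p_extinct


# ---------------------------------------------------------------------------
# Per-year likelihood elements
# ---------------------------------------------------------------------------


def test_zero_certain_rate_makes_certain_sightings_impossible():
    assert year_log_likelihood(1900, 1, 0, m1=0.0, m2=0.1, f2=0.1, extinct=False) == -np.inf
    assert year_log_likelihood(1900, 0, 0, m1=0.0, m2=0.0, f2=0.0, extinct=False) == 0.0


def test_certain_sighting_after_extinction_is_structurally_impossible():
    assert (
        year_log_likelihood(1950, 1, 0, m1=0.5, m2=0.1, f2=0.1, extinct=True, tau=1940)
        == -np.inf
    )
    # the extinction year itself still uses the pre-extinction form
    assert np.isfinite(
        year_log_likelihood(1940, 1, 0, m1=0.5, m2=0.1, f2=0.1, extinct=True, tau=1940)
    )


def test_false_sighting_rate_log2_gives_even_odds_after_extinction():
    lp = year_log_likelihood(1950, 0, 1, m1=0.5, m2=0.3, f2=np.log(2), extinct=True, tau=1940)
    assert np.exp(lp) == pytest.approx(0.5, rel=1e-12)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        year_log_likelihood(1900, 0, 0, m1=-0.1, m2=0.1, f2=0.1, extinct=False)


# ---------------------------------------------------------------------------
# MCMC against exhaustive enumeration (toy records, bounded rate prior)
# ---------------------------------------------------------------------------

TOY_TAIL = SightingRecord(  # dense certain run then a long empty tail
    frozenset({1900, 1901, 1903, 1905, 1906, 1908}), frozenset({1904, 1907}), (1900, 1919)
)
TOY_UNIFORM = SightingRecord(  # sightings spread to the window end
    frozenset({1900, 1904, 1909, 1913, 1918}), frozenset({1906, 1915}), (1900, 1919)
)


@pytest.mark.parametrize("record", [TOY_TAIL, TOY_UNIFORM], ids=["tail", "uniform"])
def test_posterior_matches_enumeration_on_toy_records(record):
    config = ModelConfig(rate_prior_upper=2.0)
    oracle_p, years, oracle_tau = enumerate_p_extinct(record, rate_upper=2.0, n_grid=48)
    summary = fit(record, config, seed=101)
    assert summary.p_extinct == pytest.approx(oracle_p, abs=0.02)
    np.testing.assert_allclose(summary.tau_probs, oracle_tau, atol=0.03)


def test_empty_tail_supports_extinction_and_uniform_record_does_not():
    config = ModelConfig(rate_prior_upper=2.0)
    p_tail = fit(TOY_TAIL, config, seed=7).p_extinct
    p_unif = fit(TOY_UNIFORM, config, seed=7).p_extinct
    assert p_tail > 0.8
    assert p_unif < 0.5
    s = fit(TOY_TAIL, config, seed=7)
    assert abs(s.tau_mode - 1908) <= 2  # change point near the last certain sighting


def test_no_uncertain_record_with_pinned_uncertain_process_matches_enumeration():
    record = SightingRecord(frozenset({1900, 1902, 1905, 1907}), frozenset(), (1900, 1919))
    config = ModelConfig(rate_prior_upper=2.0, fixed_params={"m2": 0.0, "f2": 0.0})
    oracle_p, _, _ = enumerate_p_extinct(
        record, rate_upper=2.0, n_grid=400, fixed={"m2": 0.0, "f2": 0.0}
    )
    summary = fit(record, config, seed=3)
    assert summary.p_extinct == pytest.approx(oracle_p, abs=0.02)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


def test_hyperprior_expected_value_is_half():
    assert ModelConfig().hyperprior_mean == pytest.approx(0.5)


def test_degenerate_fixed_priors_rejected(grebe):
    record, _ = grebe
    for p in (0.0, 1.0):
        with pytest.raises(ValueError, match="strictly in"):
            fit_with_fixed_prior(record, p)


def test_posterior_ordering_follows_prior_ordering(fast_config):
    record = simulate_record(SimulationSpec(seed=21))
    ps = [
        fit_with_fixed_prior(record, p, fast_config, seed=5).p_extinct
        for p in (0.1, 0.5, 0.9)
    ]
    assert ps[0] < ps[1] < ps[2]


def test_hyperprior_matches_fixed_half_prior(fast_config):
    record = simulate_record(SimulationSpec(seed=21))
    a = fit(record, fast_config, seed=9).p_extinct
    b = fit_with_fixed_prior(record, 0.5, fast_config, seed=9).p_extinct
    assert a == pytest.approx(b, abs=1e-12)  # the hyper-prior enters via its mean


def test_strong_prior_drives_posterior_toward_one(fast_config):
    record = simulate_record(SimulationSpec(seed=21))
    assert fit_with_fixed_prior(record, 0.999, fast_config, seed=5).p_extinct > 0.95


def test_trailing_empty_years_only_strengthen_extinction(fast_config):
    base = simulate_record(SimulationSpec(seed=33, T=50, tau_E=25))
    previous = -1.0
    for end in (1950, 1960, 1970):
        record = SightingRecord(base.certain_years, base.uncertain_years, (1900, end))
        p = fit(record, fast_config, seed=13).p_extinct
        assert p >= previous - 0.02  # weak monotonicity up to MC error
        previous = p


# ---------------------------------------------------------------------------
# Parameter recovery on synthetic records
# ---------------------------------------------------------------------------


def test_tau_credible_interval_coverage(fast_config):
    """90% credible intervals for the extinction year cover the truth in
    at least 80% of simulated records."""
    spec = SimulationSpec(seed=None, T=60, tau_E=30, m1=0.3, m2=0.2, f2=0.05)
    rng = np.random.default_rng(2024)
    hits = 0
    n = 50
    for _ in range(n):
        record = simulate_record(spec, rng=rng)
        summary = fit(record, fast_config, seed=int(rng.integers(2**31)))
        lo, hi = summary.credible_interval(0.9)
        hits += lo <= spec.tau_year <= hi
    assert hits / n >= 0.8
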