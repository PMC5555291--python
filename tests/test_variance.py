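"""Quality-as-variance model: fuzz algebra, nested reduction, penalty sweep."""
import numpy as np
import pytest

from resight import (
    ModelConfig,
    assign_random_quality,
    fit,
    fit_variance,
    fuzz_magnitude,
    sample_multiplier,
)
from resight.synthetic import SimulationSpec, simulate_quality, simulate_record


# ---------------------------------------------------------------------------
# Fuzz magnitude H = -a ln q
# ---------------------------------------------------------------------------


def test_fuzz_vanishes_for_certainty_or_zero_penalty():
    assert fuzz_magnitude(1.0, a=3.7) == 0.0
    assert fuzz_magnitude(0.3, a=0.0) == 0.0


def test_fuzz_log_link_value():
    assert fuzz_magnitude(np.exp(-1.0), a=2.0) == pytest.approx(2.0, rel=1e-12)


def test_fuzz_rejects_degenerate_quality():
    with pytest.raises(ValueError, match="positive"):
        fuzz_magnitude(0.0, a=1.0)
    with pytest.raises(ValueError, match="exceed"):
        fuzz_magnitude(1.2, a=1.0)
    with pytest.raises(ValueError, match="nonnegative"):
        fuzz_magnitude(0.5, a=-1.0)


# ---------------------------------------------------------------------------
# Unit-mean Gamma multiplier
# ---------------------------------------------------------------------------


def test_zero_fuzz_multiplier_is_deterministic_one():
    assert sample_multiplier(0.0) == 1.0
    np.testing.assert_array_equal(sample_multiplier(0.0, size=5), np.ones(5))


@pytest.mark.parametrize("H", [1.0, 4.0])
def test_multiplier_moments_match_gamma_identities(H):
    draws = sample_multiplier(H, seed=123, size=100_000)
    assert draws.mean() == pytest.approx(1.0, abs=0.02)
    assert draws.var() == pytest.approx(H, rel=0.05)


def test_fuzzed_rate_is_conserved_in_expectation(rng):
    """E[m2'] = m2 for every quality and penalty (unit-mean fuzz)."""
    m2 = 0.7
    for q in (0.1, 0.5, 0.9):
        for a in (0.5, 2.0, 4.0):
            r = sample_multiplier(fuzz_magnitude(q, a), seed=rng, size=200_000)
            assert (m2 * r).mean() == pytest.approx(m2, rel=0.01)


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


def _lionish(seed):
    spec = SimulationSpec(seed=seed, m2=0.4, f2=0.2)
    record = simulate_record(spec)
    return record, simulate_quality(record, spec)


def test_zero_penalty_reduces_to_base_model(fast_config):
    """At a = 0 the Gamma fuzz degenerates and the base model is recovered."""
    import dataclasses

    for seed in range(10):
        record, obs = _lionish(100 + seed)
        cfg_a0 = dataclasses.replace(fast_config, penalty_a=0.0)
        p_var = fit_variance(record, obs, cfg_a0, seed=seed).p_extinct
        p_base = fit(record, fast_config, seed=seed).p_extinct
        assert p_var == pytest.approx(p_base, abs=0.02)


def test_posterior_sd_is_nondecreasing_in_penalty(fast_config):
    import dataclasses

    record, obs = _lionish(7)
    sds = []
    for a in (0.0, 1.0, 2.0, 4.0):
        cfg = dataclasses.replace(fast_config, penalty_a=a)
        sds.append(fit_variance(record, obs, cfg, seed=11).sd_extinct)
    for lo, hi in zip(sds, sds[1:]):
        assert hi >= lo - 0.01  # non-decreasing up to MC error


def test_extreme_penalty_dissolves_the_change_point(fast_config):
    """Raising the penalty dissipates the change point into fuzz: the
    extinction-year posterior spreads monotonically toward uniformity and
    the extinction probability decays toward ignorance.  (The uncertain
    process becomes exactly uninformative in the a -> infinity limit; any
    residual concentration comes from the certain record, which quality
    never touches.)"""
    import dataclasses

    spec = SimulationSpec(seed=3, m1=0.05, m2=0.5, f2=0.1)
    record = simulate_record(spec)
    obs = simulate_quality(record, spec)
    entropies, ps = [], []
    for a in (0.0, 2.0, 10.0, 100.0):
        cfg = dataclasses.replace(fast_config, penalty_a=a)
        s = fit_variance(record, obs, cfg, seed=5)
        probs = np.clip(s.tau_probs, 1e-300, None)
        entropies.append(-(probs * np.log(probs)).sum())
        ps.append(s.p_extinct)
    assert all(hi > lo for lo, hi in zip(entropies, entropies[1:]))
    assert ps[-1] < ps[0]
    # closed-form limit: the fuzzed no-sighting factor (1 + m2 H)^(-1/H)
    # tends to 1 (uninformative) as the penalty grows
    from resight.variance import _log_mgf_term

    H = np.array([[fuzz_magnitude(0.3, a) for a in (2.0, 10.0, 1000.0)]])
    vals = np.exp(_log_mgf_term(np.array([[0.5]]), H))
    assert np.all(np.diff(vals) > 0) and vals[0, -1] > 0.99


def test_random_and_structured_quality_agree(fast_config):
    """Random quality scores change the extinction posterior little
    (median |difference| under 0.1 across synthetic records)."""
    deltas = []
    for seed in range(20):
        record, obs = _lionish(300 + seed)
        p_expert = fit_variance(record, obs, fast_config, seed=seed).p_extinct
        rand_obs = assign_random_quality(record, seed=seed)
        p_random = fit_variance(record, rand_obs, fast_config, seed=seed).p_extinct
        deltas.append(abs(p_expert - p_random))
    assert np.median(deltas) < 0.1


def test_record_without_uncertain_sightings_uses_base_likelihood(fast_config):
    from resight import SightingRecord

    record = SightingRecord(frozenset({1900, 1905, 1910}), frozenset(), (1900, 1930))
    s = fit_variance(record, [], fast_config, seed=2)
    b = fit(record, fast_config, seed=2)
    assert "no_uncertain_sightings_base_likelihood" in s.flags
    assert s.p_extinct == pytest.approx(b.p_extinct, abs=1e-12)


def test_claimed_certainty_on_uncertain_year_warns(fast_config):
    from resight import QualityObservation, SightingRecord

    record = SightingRecord(frozenset({1900, 1905}), frozenset({1903}), (1900, 1920))
    obs = [QualityObservation(1903, "point", 1.0)]
    with pytest.warns(UserWarning, match="q=1 claimed"):
        fit_variance(record, obs, fast_config, seed=1)


# ---------------------------------------------------------------------------
# Random quality assignment
# ---------------------------------------------------------------------------


def test_random_quality_is_reproducible_and_uniform(grebe):
    record, _ = grebe
    a = assign_random_quality(record, seed=5)
    b = assign_random_quality(record, seed=5)
    c = assign_random_quality(record, seed=6)
    assert [o.value for o in a] == [o.value for o in b]
    assert [o.value for o in a] != [o.value for o in c]
    assert all(0.0 < o.value < 1.0 for o in a + c)
    rng = np.random.default_rng(0)
    big = [assign_random_quality(record, seed=int(rng.integers(2**31))) for _ in range(500)]
    qs = np.array([o.value for obs in big for o in obs])
    assert qs.mean() == pytest.approx(0.5, abs=0.02)


def test_random_quality_requires_uncertain_sightings():
    from resight import SightingRecord

    record = SightingRecord(frozenset({1900, 1910}), frozenset(), (1900, 1920))
    with pytest.raises(ValueError, match="no uncertain"):
        assign_random_quality(record, seed=0)
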