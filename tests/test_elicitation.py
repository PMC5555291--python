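"""Quality-series imputation and before/after regime diagnostics."""
import numpy as np
import pytest

from resight import QualityObservation, SightingRecord, ValidationError
from resight.densities import UniformQuality
from resight.elicitation import (
    before_after_split,
    impute_series,
    quality_bayes_factor,
    read_quality_draws,
    sweep_ttest,
)


def _obs(pairs):
    return [
        QualityObservation(y, "range", v) if isinstance(v, tuple) else QualityObservation(y, "point", v)
        for y, v in pairs
    ]


# ---------------------------------------------------------------------------
# LOCF / FOCB imputation
# ---------------------------------------------------------------------------


def test_grebe_imputation_carries_nearest_sighting_density(grebe):
    record, obs = grebe
    series = impute_series(record, obs, seed=1)
    by_year = dict(zip(series.years.tolist(), zip(series.densities, series.provenance)))
    # before the first uncertain sighting (1947): carried backwards from it
    for y in range(1930, 1947):
        d, prov = by_year[y]
        assert prov == "focb" and (d.support == (0.4, 0.8))
    # after 1947 until the next sighting year: carried forward from 1947
    for y in range(1948, 1960):
        d, prov = by_year[y]
        assert prov == "locf" and (d.support == (0.4, 0.8))
    # certain years carry quality one
    for y in record.certain_years:
        d, prov = by_year[y]
        assert prov == "observed" and d.mean() == 1.0
    # draws stay inside the year's density support
    for d, q in zip(series.densities, series.draws):
        lo, hi = d.support
        assert lo - 1e-12 <= q <= hi + 1e-12


def test_imputation_is_reproducible_under_a_seed(grebe):
    record, obs = grebe
    a = impute_series(record, obs, seed=42)
    b = impute_series(record, obs, seed=42)
    c = impute_series(record, obs, seed=43)
    np.testing.assert_array_equal(a.draws, b.draws)
    assert not np.array_equal(a.draws, c.draws)


def test_all_certain_record_imputes_constant_one():
    record = SightingRecord(frozenset({1900, 1910}), frozenset(), (1900, 1920))
    series = impute_series(record, [QualityObservation(1900, "point", 1.0)], seed=0)
    np.testing.assert_array_equal(series.draws, np.ones(21))


def test_uncertain_without_quality_directs_to_ignore_mode():
    record = SightingRecord(frozenset({1900, 1910}), frozenset({1905}), (1900, 1920))
    with pytest.raises(ValidationError, match="quality_mode='ignore'"):
        impute_series(record, [], seed=0)


# ---------------------------------------------------------------------------
# Before/after pooling and the t-test sweep
# ---------------------------------------------------------------------------


def test_two_sighting_split_recovers_each_side():
    obs = _obs([(1900, (0.2, 0.4)), (1910, (0.6, 0.8))])
    before, after = before_after_split(obs, 1910)
    grid = np.linspace(0, 1, 501)
    np.testing.assert_allclose(before.pdf(grid), UniformQuality(0.2, 0.4).pdf(grid))
    np.testing.assert_allclose(after.pdf(grid), UniformQuality(0.6, 0.8).pdf(grid))


def test_split_at_first_sighting_errors():
    obs = _obs([(1900, 0.5), (1910, 0.6)])
    with pytest.raises(ValueError, match="empty 'before'"):
        before_after_split(obs, 1900)


def test_mirrored_densities_give_mirrored_modes():
    from resight.densities import TriangleDensity

    def tri(lo, m, hi):
        return TriangleDensity(lo, m, hi)

    obs = [(1900, tri(0.1, 0.15, 0.2)), (1905, tri(0.2, 0.3, 0.45)),
           (1910, tri(0.55, 0.7, 0.8)), (1915, tri(0.7, 0.8, 0.9))]
    mirrored = [(y, tri(round(1 - d.upper, 3), round(1 - d.best, 3), round(1 - d.lower, 3)))
                for y, d in obs]
    b1, a1 = before_after_split(obs, 1910)
    b2, a2 = before_after_split(mirrored, 1910)
    assert b1.mode() == pytest.approx(1 - b2.mode(), abs=2e-3)
    assert a1.mode() == pytest.approx(1 - a2.mode(), abs=2e-3)


def test_sweep_finds_strong_separation_at_first_split():
    obs = _obs([(1900, (0.85, 0.95)), (1905, (0.85, 0.95)), (1910, (0.05, 0.15)),
                (1915, (0.05, 0.15)), (1920, (0.05, 0.15))])
    first, results = sweep_ttest(obs, n_draws=500, seed=3, alternative="greater")
    assert first == 1905  # already significant comparing {1900} vs the rest
    assert results[1910] < 1e-6


def test_sweep_requires_enough_sightings_and_draws():
    obs = _obs([(1900, 0.5), (1910, 0.6)])
    with pytest.raises(ValueError, match="at least 3 sightings"):
        sweep_ttest(obs, n_draws=10, seed=0)
    with pytest.raises(ValueError, match="n_draws"):
        sweep_ttest(_obs([(1900, 0.5), (1905, 0.5), (1910, 0.5)]), n_draws=1, seed=0)


def test_single_regime_rejection_is_near_nominal():
    """Per-split false-positive rate on exchangeable qualities ~ alpha."""
    rng = np.random.default_rng(7)
    hits = 0
    reps = 250
    for _ in range(reps):
        obs = [(y, UniformQuality(0.3, 0.7)) for y in (1900, 1905, 1910)]
        _, results = sweep_ttest(obs, n_draws=80, seed=int(rng.integers(2**31)))
        hits += results[1905] < 0.05
    rate = hits / reps
    assert 0.01 <= rate <= 0.11  # 0.05 nominal, binomial noise


def test_draws_matrix_input_is_accepted(tmp_path):
    rng = np.random.default_rng(0)
    cols = {str(y): rng.uniform(0.7, 0.9, 50) for y in (1900, 1905)}
    cols["1910"] = rng.uniform(0.1, 0.3, 50)
    cols["1915"] = rng.uniform(0.1, 0.3, 50)
    import pandas as pd

    path = tmp_path / "draws.csv"
    pd.DataFrame(cols).to_csv(path, index=False)
    pairs = read_quality_draws(path)
    assert [y for y, _ in pairs] == [1900, 1905, 1910, 1915]
    first, results = sweep_ttest(pairs, n_draws=50, seed=1, alternative="greater")
    # extreme separation already separates the pools at the first candidate
    assert first == 1905 and results[1910] < 1e-6


# ---------------------------------------------------------------------------
# Quality-only Bayes factor
# ---------------------------------------------------------------------------


def test_bayes_factor_near_zero_for_one_regime():
    obs = [(y, UniformQuality(0.3, 0.7)) for y in (1900, 1905, 1910, 1915)]
    log_bf = quality_bayes_factor(obs, 1910, n_draws=400, seed=5)
    assert abs(log_bf) < 20  # small relative to the separated case below


def test_bayes_factor_diverges_negative_for_separated_regimes():
    obs = [(1900, UniformQuality(0.8, 0.9)), (1905, UniformQuality(0.8, 0.9)),
           (1910, UniformQuality(0.1, 0.2)), (1915, UniformQuality(0.1, 0.2))]
    log_bf = quality_bayes_factor(obs, 1910, n_draws=400, seed=5)
    assert log_bf < -100


def test_bayes_factor_sentinel_when_a_side_is_degenerate():
    obs = [(1900, UniformQuality(0.4, 0.6)), (1910, UniformQuality(0.4, 0.6))]
    assert np.isnan(quality_bayes_factor(obs, 1910, seed=0))
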