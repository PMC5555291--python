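"""Expert-quality pooling, quality-series imputation and regime diagnostics.

Per-sighting quality judgements are elicited from several experts as
(lower, best, upper) triangle densities for several questions; linear
opinion pooling averages them into one mixture density per sighting.
Diagnostics then ask whether the quality process itself shows a regime
change over the record: a sweep of one-sided t-tests on before/after
pooled densities, modes of the combined before/after mixtures, and an
empirical quality-only Bayes factor (one Beta regime versus two).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .densities import MixtureQuality, PointQuality, QualityDensity, TriangleDensity
from .records import QualityObservation, SightingRecord, ValidationError

__all__ = [
    "TriangleElicitation",
    "QualitySeries",
    "pool_linear",
    "read_elicitations",
    "read_quality_draws",
    "impute_series",
    "before_after_split",
    "sweep_ttest",
    "quality_bayes_factor",
    "BAYES_FACTOR_UNDEFINED",
]


@dataclass(frozen=True)
class TriangleElicitation:
    """One expert's triangle judgement for one question about one sighting."""

    lower: float
    best: float
    upper: float
    expert_id: str = "expert"
    question_id: str = "q"
    weight: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.best <= self.upper <= 1.0):
            raise ValueError(
                f"need 0 <= lower <= best <= upper <= 1; got "
                f"({self.lower}, {self.best}, {self.upper})"
            )
        if self.weight < 0:
            raise ValueError("expert competency weight must be nonnegative")

    def density(self) -> TriangleDensity:
        return TriangleDensity(self.lower, self.best, self.upper)


def pool_linear(elicitations: Sequence[TriangleElicitation]) -> MixtureQuality:
    """Linear opinion pool across experts and questions.

    The pooled density is the weighted average of the individual triangle
    densities.  Experts are treated as exchangeable (equal weights by
    default) and no inter-question correlation is modelled; note that a
    pool of triangles is not itself a triangle.
    """
    if len(elicitations) == 0:
        raise ValueError("cannot pool an empty set of elicitations")
    weights = np.array([e.weight for e in elicitations], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all pooling weights are zero; cannot normalise")
    return MixtureQuality([e.density() for e in elicitations], weights)


def read_elicitations(path) -> dict[int, list[TriangleElicitation]]:
    """Read a per-sighting elicitation table.

    CSV columns: ``sighting_year, expert_id, question_id, lower, best,
    upper[, weight]``.  Returns elicitations grouped by sighting year.
    """
    df = pd.read_csv(path)
    required = {"sighting_year", "expert_id", "question_id", "lower", "best", "upper"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: dict[int, list[TriangleElicitation]] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["sighting_year"]), []).append(
            TriangleElicitation(
                float(row["lower"]),
                float(row["best"]),
                float(row["upper"]),
                str(row["expert_id"]),
                str(row["question_id"]),
                float(row.get("weight", 1.0)) if "weight" in df.columns else 1.0,
            )
        )
    return out


def read_quality_draws(path) -> list[tuple[int, np.ndarray]]:
    """Read a draws matrix: one column per sighting (chronological), rows =
    random draws from that sighting's pooled quality density.

    Column labels are used as sighting years when they parse as integers,
    otherwise columns are numbered in order.
    """
    df = pd.read_csv(path)
    out = []
    for i, col in enumerate(df.columns):
        try:
            year = int(float(col))
        except ValueError:
            year = i
        out.append((year, df[col].dropna().to_numpy(dtype=float)))
    return out


# ---------------------------------------------------------------------------
# Quality series (LOCF / FOCB imputation)
# ---------------------------------------------------------------------------


@dataclass
class QualitySeries:
    """One quality density (and one draw) per year of the window.

    Observed uncertain years carry their own density; later years without
    an uncertain sighting inherit the density of the *last* uncertain
    sighting (LOCF), years before the first uncertain sighting inherit the
    *first* sighting's density (FOCB), and certain years carry q = 1.
    Imputed draws are random samples from the inherited density, so the
    uncertainty of the nearest sighting's quality propagates rather than a
    single carried value.
    """

    years: np.ndarray
    densities: list[QualityDensity]
    draws: np.ndarray
    provenance: list[str]  # per year: "observed" | "locf" | "focb"

    def density_groups(self) -> list[tuple[QualityDensity, np.ndarray]]:
        """Group window years sharing one density object (for fast
        marginalisation: imputed years reuse their source sighting's law)."""
        groups: dict[int, list[int]] = {}
        ref: dict[int, QualityDensity] = {}
        for i, d in enumerate(self.densities):
            groups.setdefault(id(d), []).append(i)
            ref[id(d)] = d
        return [(ref[k], np.array(v)) for k, v in groups.items()]


def impute_series(
    record: SightingRecord,
    observations: Sequence[QualityObservation],
    seed: Optional[int] = None,
) -> QualitySeries:
    """Build a full per-year quality series by randomised LOCF/FOCB.

    An all-certain record yields the constant series q = 1.  A record with
    uncertain sightings but no quality observations for them raises a
    :class:`ValidationError` (run with ``quality_mode='ignore'`` instead).
    """
    uncertain_obs = sorted(
        (o for o in observations if o.year in record.uncertain_years), key=lambda o: o.year
    )
    uncertain_obs = [o for o in uncertain_obs if o.year <= record.end_year]
    if not uncertain_obs:
        if not record.uncertain_years:
            # every sighting is certain: the quality series is identically 1
            one = PointQuality(1.0)
            years = record.years
            return QualitySeries(
                years, [one] * len(years), np.ones(len(years)), ["observed"] * len(years)
            )
        raise ValidationError(
            "record has uncertain sightings but no quality observations for them; "
            "quality-aware models need at least one — use quality_mode='ignore'"
        )
    rng = np.random.default_rng(seed)
    obs_by_year = {o.year: o for o in uncertain_obs}
    years = record.years
    densities: list[QualityDensity] = []
    provenance: list[str] = []
    one = PointQuality(1.0)
    last_density: Optional[QualityDensity] = None
    first_density = uncertain_obs[0].density()
    den_cache = {o.year: o.density() for o in uncertain_obs}
    for y in years:
        if y in obs_by_year:
            last_density = den_cache[y]
            densities.append(last_density)
            provenance.append("observed")
        elif y in record.certain_years:
            densities.append(one)
            provenance.append("observed")
        elif last_density is not None:
            densities.append(last_density)
            provenance.append("locf")
        else:
            densities.append(first_density)
            provenance.append("focb")
    draws = np.array([d.rvs(rng) for d in densities], dtype=float)
    return QualitySeries(years, densities, draws, provenance)


# ---------------------------------------------------------------------------
# Before/after diagnostics
# ---------------------------------------------------------------------------


def _sorted_densities(observations) -> list[tuple[int, QualityDensity]]:
    """Normalise input to (year, density) pairs in chronological order.

    Accepts QualityObservation sequences, (year, density) pairs, or
    (year, draws-array) pairs from a draws matrix.
    """
    out = []
    for item in observations:
        if isinstance(item, QualityObservation):
            out.append((item.year, item.density()))
        else:
            year, val = item
            out.append((int(year), val))
    return sorted(out, key=lambda p: p[0])


def _draws_from(val, n, rng) -> np.ndarray:
    if isinstance(val, PointQuality):
        # a degenerate density carries one value; replicating it n times
        # would pseudo-replicate the sighting in the t-test
        return np.array([val.q])
    if isinstance(val, QualityDensity):
        return np.asarray(val.rvs(rng, size=n), dtype=float)
    arr = np.asarray(val, dtype=float)
    return arr if n is None or len(arr) <= n else rng.choice(arr, size=n, replace=False)


def before_after_split(observations, split_year: int):
    """Pool per-sighting densities on each side of ``split_year``.

    The sighting at ``split_year`` goes to the *after* pool (which thereby
    includes the sighting in question); both pools weight their sightings
    equally.  Returns ``(before, after)`` mixture densities.
    """
    pairs = _sorted_densities(observations)
    years = [y for y, _ in pairs]
    if split_year <= years[0]:
        raise ValueError(
            f"split at {split_year} leaves an empty 'before' pool (first sighting {years[0]})"
        )
    before = [d for y, d in pairs if y < split_year]
    after = [d for y, d in pairs if y >= split_year]
    if not after:
        raise ValueError(f"split at {split_year} leaves an empty 'after' pool")
    return MixtureQuality(before), MixtureQuality(after)


def sweep_ttest(
    observations,
    n_draws: int = 1000,
    seed: Optional[int] = None,
    alternative: str = "greater",
    alpha: float = 0.05,
):
    """Sweep candidate split years and t-test before vs after quality.

    For each sighting year (excluding the first) the before/after pooled
    densities are sampled ``n_draws`` times each and compared with a
    two-sample t-test.  ``alternative`` is the direction of the one-sided
    test in scipy convention for (before, after): "greater" tests
    before > after (quality drops after extinction), "less" the reverse,
    "two-sided" is available since a quality *rise* after the change is
    empirically possible.

    Returns ``(first_significant_year, results)`` where ``results`` maps
    split year -> p-value; the first year with p < ``alpha`` is reported,
    or ``None`` if the sweep never reaches significance.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    pairs = _sorted_densities(observations)
    if len(pairs) < 3:
        raise ValueError("need at least 3 sightings to sweep for a quality change")
    rng = np.random.default_rng(seed)
    results: dict[int, float] = {}
    first = None
    for split_year in [y for y, _ in pairs[1:]]:
        if split_year in results:
            continue
        before = np.concatenate(
            [_draws_from(v, n_draws, rng) for y, v in pairs if y < split_year]
        )
        after = np.concatenate(
            [_draws_from(v, n_draws, rng) for y, v in pairs if y >= split_year]
        )
        p = stats.ttest_ind(before, after, equal_var=False, alternative=alternative).pvalue
        results[split_year] = float(p)
        if first is None and p < alpha:
            first = split_year
    return first, results


BAYES_FACTOR_UNDEFINED = float("nan")


def _beta_loglik(x: np.ndarray) -> float:
    eps = 1e-6
    x = np.clip(x, eps, 1 - eps)
    a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    return float(np.sum(stats.beta.logpdf(x, a, b)))


def quality_bayes_factor(
    observations,
    split_year: int,
    n_draws: int = 200,
    seed: Optional[int] = None,
) -> float:
    """Empirical log Bayes factor for the quality data alone at a split.

    Compares the likelihood of all quality values under a single Beta law
    (one regime: species extant throughout, the quality process unchanged)
    against separate Beta laws fitted before/after the split (two regimes:
    extinction changed the quality process).  Shape parameters are fitted
    by maximum likelihood, so this is an empirical (plug-in) Bayes factor.

    On one-regime data the log Bayes factor is approximately zero; strongly
    separated regimes drive it toward minus infinity (the one-regime
    likelihood collapses).  With fewer than two sightings on either side
    the ratio is undefined and NaN is returned.
    """
    pairs = _sorted_densities(observations)
    rng = np.random.default_rng(seed)
    before = [v for y, v in pairs if y < split_year]
    after = [v for y, v in pairs if y >= split_year]
    if len(before) < 2 or len(after) < 2:
        return BAYES_FACTOR_UNDEFINED
    b = np.concatenate([_draws_from(v, n_draws, rng) for v in before])
    a = np.concatenate([_draws_from(v, n_draws, rng) for v in after])
    pooled = np.concatenate([b, a])
    return _beta_loglik(pooled) - (_beta_loglik(b) + _beta_loglik(a))
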