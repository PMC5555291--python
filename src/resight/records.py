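"""Sighting-record containers, validation, windowing and CSV I/O.

A sighting record is an annual time series over an observation window
``(start_year, end_year)``.  Each year carries two binary flags: a *certain*
sighting (verified evidence, e.g. a specimen) and an *uncertain* sighting
(an unverified report).  The change-point models treat the two flag series
as parallel Bernoulli processes with per-year occupancy probabilities of
the form ``1 - exp(-rate)``, so multiple same-year reports collapse to one
flag per process.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .densities import PointQuality, QualityDensity, UniformQuality

__all__ = [
    "SightingRecord",
    "QualityObservation",
    "ModelConfig",
    "ValidationError",
    "read_record",
    "write_record",
    "truncate_record",
]


class ValidationError(ValueError):
    """A sighting record violates a structural requirement of the model."""


@dataclass(frozen=True)
class SightingRecord:
    """Annual certain/uncertain sighting flags over an observation window.

    Parameters
    ----------
    certain_years, uncertain_years
        Calendar years flagged for each process.  A year may carry both
        flags.  Flags are binary: repeated sightings in one year collapse.
    window
        ``(start_year, end_year)`` inclusive.  The model's time axis is
        ``t = year - start_year`` on ``(0, T)`` with ``T = end - start``.
    """

    certain_years: frozenset[int]
    uncertain_years: frozenset[int]
    window: tuple[int, int]

    def __post_init__(self):
        object.__setattr__(self, "certain_years", frozenset(int(y) for y in self.certain_years))
        object.__setattr__(self, "uncertain_years", frozenset(int(y) for y in self.uncertain_years))
        start, end = self.window
        if end < start:
            raise ValidationError(f"window end {end} precedes window start {start}")
        for y in self.certain_years | self.uncertain_years:
            if not (start <= y <= end):
                raise ValidationError(
                    f"flagged year {y} lies outside the observation window {self.window}"
                )

    # -- derived views -------------------------------------------------
    @property
    def start_year(self) -> int:
        return self.window[0]

    @property
    def end_year(self) -> int:
        return self.window[1]

    @property
    def T(self) -> int:
        """Length of the observation window in years (end - start)."""
        return self.end_year - self.start_year

    @property
    def n_years(self) -> int:
        return self.T + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def s1(self) -> np.ndarray:
        """Binary certain-sighting indicator per window year."""
        out = np.zeros(self.n_years, dtype=np.int8)
        out[[y - self.start_year for y in self.certain_years]] = 1
        return out

    @property
    def s2(self) -> np.ndarray:
        """Binary uncertain-sighting indicator per window year."""
        out = np.zeros(self.n_years, dtype=np.int8)
        out[[y - self.start_year for y in self.uncertain_years]] = 1
        return out

    @property
    def last_certain_year(self) -> int:
        return max(self.certain_years)

    @property
    def is_fittable(self) -> bool:
        try:
            self.validate()
        except ValidationError:
            return False
        return True

    def validate(self) -> "SightingRecord":
        """Enforce the model's structural requirements.

        The change-point likelihood needs a certain record with at least
        two sightings, anchored at the start of the window.
        """
        if len(self.certain_years) < 2:
            raise ValidationError(
                "a certain sighting record with at least two sightings is required; "
                f"got {sorted(self.certain_years)}"
            )
        if self.start_year not in self.certain_years:
            raise ValidationError(
                f"the first year of the window ({self.start_year}) must carry a "
                "certain sighting"
            )
        return self


@dataclass(frozen=True)
class QualityObservation:
    """Quality of one sighting: a point score, a range, or a full density.

    ``q = 1`` denotes a certain sighting; uncertain sightings have
    ``q in [0, 1)`` (strictly positive when used by the variance method,
    whose fuzz magnitude is ``-a ln q``).
    """

    year: int
    kind: str  # {"point", "range", "density"}
    value: object  # float | (lo, hi) | QualityDensity

    def __post_init__(self):
        if self.kind == "point":
            q = float(self.value)
            if not (0.0 <= q <= 1.0):
                raise ValidationError(f"quality {q} outside [0, 1] in year {self.year}")
        elif self.kind == "range":
            lo, hi = self.value
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError(
                    f"quality range ({lo}, {hi}) invalid in year {self.year}: need 0 <= lo < hi <= 1"
                )
        elif self.kind == "density":
            if not isinstance(self.value, QualityDensity):
                raise ValidationError("kind='density' requires a QualityDensity value")
        else:
            raise ValidationError(f"unknown quality kind {self.kind!r}")

    def density(self) -> QualityDensity:
        """The quality law this observation encodes."""
        if self.kind == "point":
            return PointQuality(float(self.value))
        if self.kind == "range":
            lo, hi = self.value
            return UniformQuality(lo, hi)
        return self.value


@dataclass
class ModelConfig:
    """Sampler settings, priors and quality handling shared by all models.

    Attributes
    ----------
    extinction_hyperprior
        Beta shape parameters of the non-informative hyper-prior on the
        prior extinction probability.  The default Jeffreys Beta(0.5, 0.5)
        has expected value 0.5 — an evens bet of prior ignorance.
    rate_prior_upper
        Upper bound of the wide uniform priors on the sighting rates
        m1, m2 and the false-sighting offset f2.
    penalty_a
        Quality penalty of the variance method: fuzz magnitude is
        ``-a ln q``.  ``a = 0`` disables quality entirely.
    quality_mode
        "ignore", "breakpoint" or "variance".
    range_handling
        How Uniform(lo, hi) quality ranges enter the likelihood:
        "integrate" marginalises over the range, "midpoint" fixes the
        midpoint value.
    tau_prior
        Normalisation of the uniform extinction-year prior: "window"
        spreads it over every year of the observation window (years before
        the last certain sighting carry zero likelihood and only dilute
        the extinct branch), "support" restricts it to the years that can
        actually be the change point.
    tau_estimator
        Point summary of the extinction-year posterior: "mode" (posterior
        mode, ties broken to the earlier year), "mean" or "median".
    """

    extinction_hyperprior: tuple[float, float] = (0.5, 0.5)
    rate_prior_upper: float = 100.0
    penalty_a: float = 2.0
    quality_mode: str = "ignore"
    iterations: int = 10_000
    burn_in: int = 2_000
    chains: int = 4
    seed: Optional[int] = None
    rhat_threshold: float = 1.05
    range_handling: str = "integrate"
    tau_prior: str = "window"
    tau_estimator: str = "mode"
    quad_points: int = 16
    min_uncertain_breakpoint: int = 10
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.penalty_a < 0:
            raise ValueError("penalty_a must be nonnegative")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for convergence checks")
        if self.quality_mode not in ("ignore", "breakpoint", "variance"):
            raise ValueError(f"unknown quality_mode {self.quality_mode!r}")
        if self.tau_prior not in ("window", "support"):
            raise ValueError(f"unknown tau_prior {self.tau_prior!r}")

    @property
    def hyperprior_mean(self) -> float:
        """Expected value of the extinction hyper-prior (0.5 for Jeffreys)."""
        a, b = self.extinction_hyperprior
        return a / (a + b)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["year", "certainty", "q", "q_lo", "q_hi", "location"]


def read_record(
    path,
    end_year: Optional[int] = None,
    validate: bool = True,
) -> tuple[SightingRecord, list[QualityObservation]]:
    """Read a sighting table from CSV.

    Expected columns: ``year``, ``certainty`` ("certain"/"uncertain") and
    quality columns ``q`` or ``q_lo``/``q_hi`` (blank ``q`` when a range is
    given).  An optional free-text ``location`` column is carried but
    unused by any model.

    The window starts at the first certain sighting (the model requires a
    certain anchor); uncertain sightings before it are dropped with a
    warning.  The window ends at ``end_year`` (default: last sighting).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty sighting table")
    missing = {"year", "certainty"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")

    certain, uncertain, observations = set(), set(), []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after header
        year = int(row["year"])
        cert = str(row["certainty"]).strip().lower()
        if cert not in ("certain", "uncertain"):
            raise ValidationError(f"{path} row {rowno}: certainty must be certain/uncertain")
        q = row.get("q", np.nan)
        q_lo = row.get("q_lo", np.nan)
        q_hi = row.get("q_hi", np.nan)
        if cert == "certain":
            certain.add(year)
            if np.isfinite(q) and float(q) != 1.0:
                raise ValidationError(
                    f"{path} row {rowno}: a quality score of 1 indicates a certain "
                    f"sighting; got q={q} on a certain row"
                )
            observations.append(QualityObservation(year, "point", 1.0))
        else:
            uncertain.add(year)
            if np.isfinite(q_lo) or np.isfinite(q_hi):
                if not (np.isfinite(q_lo) and np.isfinite(q_hi)):
                    raise ValidationError(f"{path} row {rowno}: q_lo/q_hi must both be given")
                lo, hi = float(q_lo), float(q_hi)
                if not (0.0 <= lo < hi <= 1.0):
                    raise ValidationError(
                        f"{path} row {rowno}: quality range ({lo}, {hi}) outside [0, 1]"
                    )
                observations.append(QualityObservation(year, "range", (lo, hi)))
            elif np.isfinite(q):
                qv = float(q)
                if not (0.0 <= qv <= 1.0):
                    raise ValidationError(f"{path} row {rowno}: quality {qv} outside [0, 1]")
                if qv == 1.0:
                    raise ValidationError(
                        f"{path} row {rowno}: q=1 is reserved for certain sightings"
                    )
                observations.append(QualityObservation(year, "point", qv))
            # uncertain rows may legitimately carry no quality (quality_mode=ignore)

    if not certain:
        raise ValidationError(
            f"{path}: no certain sightings; a certain record with at least two "
            "sightings is required"
        )
    start = min(certain)
    dropped = sorted(y for y in uncertain if y < start)
    if dropped:
        warnings.warn(
            f"{path}: uncertain sightings {dropped} precede the first certain "
            f"sighting ({start}) and fall outside the observation window; dropped",
            stacklevel=2,
        )
        uncertain -= set(dropped)
        observations = [o for o in observations if o.year >= start]
    end = int(end_year) if end_year is not None else max(certain | uncertain)
    record = SightingRecord(frozenset(certain), frozenset(uncertain), (start, end))
    if validate:
        record.validate()
    return record, observations


def write_record(record: SightingRecord, observations: Sequence[QualityObservation], path) -> None:
    """Write a sighting table to CSV (inverse of :func:`read_record`)."""
    by_year = {o.year: o for o in observations}
    rows = []
    for year in sorted(record.certain_years | record.uncertain_years):
        cert = "certain" if year in record.certain_years else "uncertain"
        q = q_lo = q_hi = ""
        obs = by_year.get(year)
        if cert == "certain":
            q = 1.0
        elif obs is not None:
            if obs.kind == "point":
                q = float(obs.value)
            elif obs.kind == "range":
                q_lo, q_hi = obs.value
        rows.append({"year": year, "certainty": cert, "q": q, "q_lo": q_lo, "q_hi": q_hi})
    pd.DataFrame(rows, columns=["year", "certainty", "q", "q_lo", "q_hi"]).to_csv(
        path, index=False
    )


def truncate_record(record: SightingRecord, year: int) -> SightingRecord:
    """Restrict a record to sightings at or before ``year``.

    This is the "data as it stands in ``year``" view used by the sequential
    runner.  The window end is set to ``year``.  The result may fail
    :meth:`SightingRecord.validate` (e.g. fewer than two certain sightings
    survive); callers decide whether such a record is fittable.
    """
    if year < record.start_year:
        raise ValidationError(
            f"truncation year {year} precedes the window start {record.start_year}"
        )
    year = min(year, record.end_year)
    return replace(
        record,
        certain_years=frozenset(y for y in record.certain_years if y <= year),
        uncertain_years=frozenset(y for y in record.uncertain_years if y <= year),
        window=(record.start_year, year),
    )
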