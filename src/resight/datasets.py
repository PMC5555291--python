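"""Built-in sighting records for three candidate-extinct bird species.

These are the published annual sighting compilations (BirdLife International
quality classifications) routinely used to exercise sighting-record
extinction models: the Alaotra grebe (*Tachybaptus rufolavatus*), Jamaican
petrel (*Pterodroma caribbaea*) and Pohnpei starling (*Aplonis pelzelni*).
A quality of 1 marks a certain sighting; uncertain sightings carry a
uniform quality range.

The Barbary lion (*Panthera l. leo*) record — 32 alleged sightings between
1895 and 1956 with per-sighting pooled expert quality densities — is *not*
shipped: the sighting years are not in the public tables available here, so
lion-like data must be produced with :mod:`resight.synthetic`.
"""
from __future__ import annotations

from .records import QualityObservation, SightingRecord

__all__ = ["load_bird", "BIRDS", "DEFAULT_END_YEAR", "EXTERNAL_DATA_CHECKS"]

DEFAULT_END_YEAR = 2016  # the records "as they stand" for full-dataset runs

_TABLES = {
    # year: quality (1.0 = certain, (lo, hi) = uncertain range)
    "alaotra_grebe": {
        1929: 1.0,
        1947: (0.4, 0.8),
        1960: 1.0,
        1963: 1.0,
        1969: 1.0,
        1970: (0.1, 0.4),
        1971: (0.1, 0.4),
        1972: (0.6, 0.8),
        1982: (0.6, 0.8),
        1985: (0.6, 0.8),
        1986: (0.1, 0.4),
        1988: (0.1, 0.4),
    },
    "jamaican_petrel": {
        1789: 1.0,  # first sighting of the record: assumed certain (window anchor)
        1829: 1.0,
        1847: (0.4, 0.8),
        1866: 1.0,
        1879: 1.0,
        1891: (0.8, 0.9),
    },
    "pohnpei_starling": {
        1930: 1.0,
        1995: 1.0,
        2008: (0.4, 0.8),
    },
}

BIRDS = tuple(sorted(_TABLES))

# Reported quantities for the Barbary lion cannot be recomputed from shipped
# data: the 32 sighting years and the per-sighting expert quality densities
# exist only in external supplementary material.  They are listed here as
# external-data checks; the quality t-test sweep can be run if a draws
# matrix (one column per sighting, chronological) is supplied to
# ``elicitation.sweep_ttest`` via ``read_quality_draws``.
EXTERNAL_DATA_CHECKS = {
    "barbary_lion": {
        "requires": "32 sighting years 1895-1956 + per-sighting quality densities",
        "overwhelm_year": 1953,
        "full_dataset_extinction_year": 1954,
        "breakpoint_overwhelm_year": 1969,
        "prior_sensitivity_extinction_years": {0.9: 1936, 0.5: 1931, 0.1: 1924},
        "quality_ttest_change_year": 1929,
    }
}


def load_bird(
    name: str, end_year: int = DEFAULT_END_YEAR
) -> tuple[SightingRecord, list[QualityObservation]]:
    """Load one bird record by name (see :data:`BIRDS`).

    The window runs from the record's first sighting to ``end_year``.  The
    change-point likelihood needs a certain sighting to anchor the window,
    so a record whose first sighting was reported without verification (the
    petrel's 1789 report) follows the standard anchoring assumption that
    the record-opening sighting is certain — the same convention applied to
    the Barbary lion's 1895 first sighting.
    """
    try:
        table = _TABLES[name]
    except KeyError:
        raise KeyError(f"unknown record {name!r}; available: {', '.join(BIRDS)}") from None
    certain = {y for y, q in table.items() if q == 1.0}
    start = min(certain)
    uncertain = {y for y, q in table.items() if q != 1.0 and y >= start}
    record = SightingRecord(frozenset(certain), frozenset(uncertain), (start, end_year))
    observations = [
        QualityObservation(y, "point", 1.0) if q == 1.0 else QualityObservation(y, "range", q)
        for y, q in sorted(table.items())
        if y >= start
    ]
    return record.validate(), observations
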