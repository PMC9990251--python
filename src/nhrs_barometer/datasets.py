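"""Bundled reference data: the Mauritius 2020 observation and the
published 2014/2018 round scores it is compared against.

The 2020 observation carries the survey inputs behind the published
scorecard: 4 universities/colleges conducting research for health, 40
technical and support staff in the research programme, 89 peer-reviewed
publications in the 1 Dec 2019 – 30 Nov 2020 window, a population of
1,267,000, and a research allocation of Rs 38,395,000 out of a Rs 11.7
billion health ministry budget.

The 2014 and 2018 scores are stored as opaque historical percentages
(their underlying sub-function data were not re-collected), keyed by the
same labels the comparison module uses.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .scoring import RawObservation

_DATA = resources.files("nhrs_barometer") / "data"


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(_DATA / name))


def default_schema_path() -> Path:
    return data_path("default_schema.json")


def mauritius_2020_csv_path() -> Path:
    return data_path("mauritius_2020.csv")


def mauritius_2020() -> RawObservation:
    """The Mauritius 2020 survey observation."""
    return RawObservation(
        country="Mauritius",
        year=2020,
        population=1_267_000,
        r4h_budget=38_395_000.0,
        total_health_budget=11_700_000_000.0,
        binary_flags={
            "r4h_policy": 0,
            "r4h_legislation": 1,
            "r4h_strategic_plan": 0,
            "ethics_committee": 1,
            "research_focal_point": 1,
            "prioritized_agenda": 0,
            "research_programme": 1,
            "internet_connectivity": 1,
            "research_council": 1,
            "ngo_r4h": 1,
            "research_forum": 0,
            "knowledge_translation": 1,
            "budget_line": 1,
        },
        counts={
            "staff_per_100k": 40,
            "universities_per_million": 4,
            "pubs_per_100k": 89,
        },
    )


def historical_scores() -> dict[int, dict[str, float]]:
    """Published Mauritius round scores (percent) by year and label.

    Only the scores the earlier rounds reported are present; missing
    labels are simply incomparable in temporal analyses.
    """
    return {
        2014: {
            "overall": 19.0,
            "leadership_governance": 33.3,
            "developing_resources": 20.83,
            "producing_utilizing": 4.214,
        },
        2018: {
            "overall": 44.0,
            "producing_utilizing": 53.758,
            "financing": 50.013,
        },
    }
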