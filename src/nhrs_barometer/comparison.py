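"""Temporal change analysis and cohort-derived goalposts.

Assessment rounds are compared both in percentage points (absolute change)
and as percent of the baseline score (relative change); published
assessments mix the two framings, so exports label them unambiguously.

Cohort goalposts implement the benchmark-country rule: the maximum actual
score an indicator attains across a cohort becomes its goalpost_max, so
the benchmark country's own index for that indicator is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from .barometer import ScoreCard, scorecard_scores
from .errors import DomainError, UndefinedChangeError
from .schema import BarometerSchema, GoalpostSource, IndicatorSpec
from .scoring import ActualScore

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemporalComparison:
    """Change in one score (overall or one function) between two rounds.

    ``relative_change`` is ``None`` when the baseline score is 0, where
    percent-of-baseline change is undefined.
    """

    label: str
    baseline_year: int
    baseline_score: float
    current_year: int
    current_score: float
    absolute_change: float
    relative_change: Optional[float]


@dataclass(frozen=True)
class ComparisonResult:
    comparisons: tuple[TemporalComparison, ...]
    only_baseline: tuple[str, ...]
    only_current: tuple[str, ...]


@dataclass(frozen=True)
class CohortGoalposts:
    """A cohort-derived goalpost_max and the country that set it."""

    indicator_id: str
    derived_max: float
    benchmark_country: str
    cohort_size: int


def relative_change(baseline: float, current: float) -> float:
    """Percent-of-baseline change: ``(current - baseline) / baseline * 100``.

    Negative when the score declined. Undefined (raises) at baseline 0.
    """
    if baseline <= 0:
        raise UndefinedChangeError(
            f"relative change undefined for baseline {baseline} (must be > 0)"
        )
    return (current - baseline) / baseline * 100.0


ScoreSet = Union[ScoreCard, Mapping[str, float]]


def _as_scores(scores: ScoreSet) -> Mapping[str, float]:
    if isinstance(scores, ScoreCard):
        return scorecard_scores(scores)
    return scores


def compare_timepoints(
    baseline: ScoreSet,
    current: ScoreSet,
    *,
    baseline_year: Optional[int] = None,
    current_year: Optional[int] = None,
) -> ComparisonResult:
    """Compare two labelled score sets (ScoreCards or label→percent maps).

    One :class:`TemporalComparison` is produced per shared label; labels
    present in only one set are reported as incomparable, not errors. Years
    are taken from the ScoreCards when not given explicitly; identical
    years are an input error.
    """
    if baseline_year is None:
        if not isinstance(baseline, ScoreCard):
            raise DomainError("baseline_year required when baseline is not a ScoreCard")
        baseline_year = baseline.year
    if current_year is None:
        if not isinstance(current, ScoreCard):
            raise DomainError("current_year required when current is not a ScoreCard")
        current_year = current.year
    if baseline_year == current_year:
        raise DomainError(f"both score sets are labelled year {baseline_year}")

    base = _as_scores(baseline)
    curr = _as_scores(current)
    shared = [k for k in base if k in curr]
    only_base = tuple(k for k in base if k not in curr)
    only_curr = tuple(k for k in curr if k not in base)
    if "overall" not in base or "overall" not in curr:
        raise DomainError("both score sets must cover the overall score")
    for label in only_base + only_curr:
        log.warning("label '%s' present in only one round; reported as incomparable", label)

    comparisons = []
    for label in shared:
        b, c = float(base[label]), float(curr[label])
        rel = relative_change(b, c) if b > 0 else None
        comparisons.append(
            TemporalComparison(
                label=label,
                baseline_year=baseline_year,
                baseline_score=b,
                current_year=current_year,
                current_score=c,
                absolute_change=c - b,
                relative_change=rel,
            )
        )
    return ComparisonResult(tuple(comparisons), only_base, only_curr)


def derive_cohort_goalposts(
    indicator: IndicatorSpec,
    cohort: Sequence[tuple[str, Union[ActualScore, float]]],
) -> CohortGoalposts:
    """Benchmark rule: goalpost_max = the cohort's maximum actual score.

    ``cohort`` is a sequence of ``(country, actual score)`` pairs. Ties
    break to the first country in input order (and are logged). Only valid
    for indicators whose goalposts are declared ``cohort_max``.
    """
    if indicator.goalpost_source is not GoalpostSource.cohort_max:
        raise DomainError(
            f"indicator '{indicator.id}' has {indicator.goalpost_source.value} goalposts; "
            "cohort derivation applies only to cohort_max indicators"
        )
    if not cohort:
        raise DomainError(f"indicator '{indicator.id}': cohort is empty")
    values = [
        (country, a.value if isinstance(a, ActualScore) else float(a))
        for country, a in cohort
    ]
    best_country, best = values[0]
    for country, v in values[1:]:
        if v > best:
            best_country, best = country, v
        elif v == best:
            log.info(
                "cohort tie at %.6g between '%s' and '%s'; keeping first",
                best, best_country, country,
            )
    return CohortGoalposts(
        indicator_id=indicator.id,
        derived_max=best,
        benchmark_country=best_country,
        cohort_size=len(values),
    )


def apply_cohort_goalposts(
    schema: BarometerSchema, derived: CohortGoalposts
) -> BarometerSchema:
    """Return a schema with the indicator's goalpost_max replaced by the
    cohort-derived maximum (benchmark noted)."""
    indicators = []
    for ind in schema.indicators:
        if ind.id == derived.indicator_id:
            ind = ind.model_copy(
                update={
                    "goalpost_max": derived.derived_max,
                    "benchmark_note": f"{derived.benchmark_country} (cohort of {derived.cohort_size})",
                }
            )
        indicators.append(ind)
    return schema.model_copy(update={"indicators": indicators})
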