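"""Index normalisation, aggregation, performance bands, and gaps.

Each sub-function's actual score is min–max normalised against its
goalposts, in the style of the Human Development Index::

    index = (actual - goalpost_min) / (goalpost_max - goalpost_min)

clamped to [0, 1] (cohort-derived goalposts are historical benchmarks a
future observation can exceed). Function scores are the unweighted mean of
their own sub-function indices times 100; the overall barometer score is
the unweighted mean of all sub-function indices times 100. Because the
four functions hold different numbers of indicators (6/6/3/2 in the
default schema), the overall score equals the indicator-count-weighted —
not the plain — mean of the function scores.

Two precision modes are offered:

``exact`` (default)
    full floating-point precision throughout;
``as_printed``
    actual scores rounded half-up to 3 decimals and indices to 4 decimals
    before aggregation, reproducing scorecards computed from printed
    (spreadsheet-rounded) intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Literal, Sequence, Union

from ._util import round_half_up
from .errors import DomainError
from .schema import BarometerSchema
from .scoring import MissingMode, RawObservation, actual_score

log = logging.getLogger(__name__)

PrecisionMode = Literal["exact", "as_printed"]

#: Absolute tolerance when testing a score against a band endpoint.
BAND_TOL = 1e-9


class PerformanceBand(str, Enum):
    """Qualitative class of a barometer score."""

    nonexistent = "nonexistent"      # 0
    below_average = "below_average"  # (0, 50)
    average = "average"              # 50
    above_average = "above_average"  # (50, 100)
    optimal = "optimal"              # 100


@dataclass(frozen=True)
class SubFunctionIndex:
    """One normalised sub-function value in [0, 1].

    ``clamped`` records that the raw index fell outside [0, 1] before
    clamping (actual beyond a goalpost). ``actual`` keeps the pre-
    normalisation value for rendering.
    """

    indicator_id: str
    index: float
    clamped: bool = False
    actual: float = float("nan")


@dataclass(frozen=True)
class ScoreCard:
    """All indices, function scores, overall score, band and gaps for one country-year."""

    country: str
    year: int
    sub_indices: tuple[SubFunctionIndex, ...]
    function_scores: dict[str, float]
    overall_score: float
    band: PerformanceBand
    gaps: dict[str, float]
    index_sum: float
    precision_mode: PrecisionMode = "exact"


IndexLike = Union[SubFunctionIndex, float]


def _values(indices: Iterable[IndexLike]) -> list[float]:
    return [i.index if isinstance(i, SubFunctionIndex) else float(i) for i in indices]


def minmax_index(
    actual: float,
    goalpost_min: float,
    goalpost_max: float,
    *,
    indicator_id: str = "",
) -> SubFunctionIndex:
    """Min–max normalise ``actual`` against the goalposts, clamped to [0, 1]."""
    if not goalpost_max > goalpost_min:
        raise DomainError(
            f"indicator '{indicator_id}': goalpost_max ({goalpost_max}) must exceed "
            f"goalpost_min ({goalpost_min})"
        )
    raw = (actual - goalpost_min) / (goalpost_max - goalpost_min)
    clamped = raw < 0.0 or raw > 1.0
    if clamped:
        log.warning(
            "index for '%s' clamped: raw %.6g outside [0, 1]", indicator_id, raw
        )
    return SubFunctionIndex(
        indicator_id=indicator_id,
        index=min(1.0, max(0.0, raw)),
        clamped=clamped,
        actual=actual,
    )


def function_score(indices: Sequence[IndexLike]) -> float:
    """Arithmetic mean of the sub-function indices, times 100 (percent)."""
    values = _values(indices)
    if not values:
        raise DomainError("function_score requires at least one sub-function index")
    return sum(values) / len(values) * 100.0


def overall_score(indices: Sequence[IndexLike]) -> float:
    """Overall barometer score: mean of all sub-function indices, times 100."""
    values = _values(indices)
    if not values:
        raise DomainError("overall_score requires at least one sub-function index")
    return sum(values) / len(values) * 100.0


def classify_band(score: float) -> PerformanceBand:
    """Band a score: 0 nonexistent, (0,50) below average, 50 average,
    (50,100) above average, 100 optimal. Endpoint equality is tested with
    absolute tolerance 1e-9; scores are not pre-rounded."""
    if score < -BAND_TOL or score > 100.0 + BAND_TOL:
        raise DomainError(f"score {score} outside [0, 100]")
    if abs(score) <= BAND_TOL:
        return PerformanceBand.nonexistent
    if abs(score - 50.0) <= BAND_TOL:
        return PerformanceBand.average
    if abs(score - 100.0) <= BAND_TOL:
        return PerformanceBand.optimal
    if score < 50.0:
        return PerformanceBand.below_average
    return PerformanceBand.above_average


def performance_gap(score: float) -> float:
    """Shortfall from optimal performance: ``100 - score``."""
    if score < -BAND_TOL or score > 100.0 + BAND_TOL:
        raise DomainError(f"score {score} outside [0, 100]")
    return 100.0 - score


def score_country(
    schema: BarometerSchema,
    obs: RawObservation,
    *,
    precision: PrecisionMode = "exact",
    missing: MissingMode = "strict",
) -> ScoreCard:
    """Run the full pipeline for one observation: actual scores →
    normalised indices → function scores → overall score, band and gaps.

    Pure function of ``(schema, obs)``: identical inputs yield identical
    scorecards.
    """
    subs: list[SubFunctionIndex] = []
    for ind in schema.ordered_indicators():
        try:
            a = actual_score(ind, obs, missing=missing).value
        except DomainError as exc:
            raise DomainError(f"indicator '{ind.id}' ({obs.country} {obs.year}): {exc}") from exc
        if precision == "as_printed":
            rounded = round_half_up(a, 3)
            if rounded != a:
                log.info("as_printed: actual '%s' %.6g -> %.3f", ind.id, a, rounded)
            a = rounded
        sfi = minmax_index(a, ind.goalpost_min, ind.goalpost_max, indicator_id=ind.id)
        if precision == "as_printed":
            sfi = replace(sfi, index=round_half_up(sfi.index, 4))
        subs.append(sfi)

    by_id = {s.indicator_id: s for s in subs}
    function_scores = {
        fn.id: function_score([by_id[i] for i in fn.indicator_ids])
        for fn in schema.functions
    }
    overall = overall_score(subs)
    gaps = {fid: performance_gap(s) for fid, s in function_scores.items()}
    gaps["overall"] = performance_gap(overall)
    return ScoreCard(
        country=obs.country,
        year=obs.year,
        sub_indices=tuple(subs),
        function_scores=function_scores,
        overall_score=overall,
        band=classify_band(overall),
        gaps=gaps,
        index_sum=sum(s.index for s in subs),
        precision_mode=precision,
    )


def scorecard_scores(card: ScoreCard) -> dict[str, float]:
    """Flat label → percent mapping ('overall' plus one entry per function)."""
    return {"overall": card.overall_score, **card.function_scores}
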