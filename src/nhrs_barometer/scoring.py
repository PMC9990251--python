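"""Actual scores: turn raw survey observations into indicator values.

Binary sub-functions score 1 if the structure exists and 0 if it does not.
Continuous sub-functions are computed from the observation's counts and
budgets:

* per-capita rates, ``count / population * scale`` with scale 100,000
  (research staff, publications) or 1,000,000 (universities);
* the budget share, ``allocation / total_budget * 100`` percent.

All arithmetic is done in full floating-point precision; rounding is a
presentation concern handled by the aggregation layer's precision modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional

import pandas as pd

from ._util import atomic_write_text
from .errors import DomainError, MissingDataError, UnknownColumnError
from .schema import BarometerSchema, IndicatorKind, IndicatorSpec, Scaling

log = logging.getLogger(__name__)

#: Columns every observation table must carry, in canonical order.
BASE_COLUMNS = ("country", "year", "population", "r4h_budget", "total_health_budget")

MissingMode = Literal["strict", "permissive"]


@dataclass
class RawObservation:
    """One country-year of survey inputs.

    ``binary_flags`` maps binary indicator ids to 0/1 (or ``None`` when the
    survey item is explicitly missing); ``counts`` maps count-based
    indicator ids (staff, universities, publications) to head counts.
    Budgets are in national currency units; no FX conversion is attempted.
    """

    country: str
    year: int
    population: int
    r4h_budget: float
    total_health_budget: float
    binary_flags: dict[str, Optional[int]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise DomainError(f"{self.country} {self.year}: population must be positive")
        if self.total_health_budget <= 0:
            raise DomainError(f"{self.country} {self.year}: total_health_budget must be positive")
        if self.r4h_budget < 0:
            raise DomainError(f"{self.country} {self.year}: r4h_budget must be non-negative")
        for iid, c in self.counts.items():
            if c < 0:
                raise DomainError(f"{self.country} {self.year}: count '{iid}' must be non-negative")
        for iid, flag in self.binary_flags.items():
            if flag is not None and flag not in (0, 1):
                raise DomainError(
                    f"{self.country} {self.year}: flag '{iid}' must be 0, 1 or missing, got {flag!r}"
                )


@dataclass(frozen=True)
class ActualScore:
    """An indicator's raw value before normalisation, with its unit."""

    indicator_id: str
    value: float
    unit: str


def rate_per_population(count: int, population: int, scale: int) -> float:
    """Events per ``scale`` population: ``count / population * scale``.

    Exact floating-point arithmetic, no rounding.
    """
    if population <= 0:
        raise DomainError("population must be positive")
    if count < 0:
        raise DomainError("count must be non-negative")
    if scale <= 0:
        raise DomainError("scale must be positive")
    return count / population * scale


def budget_share_percent(allocation: float, total: float) -> float:
    """Allocation as a percentage of the total budget (same currency)."""
    if total <= 0:
        raise DomainError("total budget must be positive")
    if allocation < 0:
        raise DomainError("allocation must be non-negative")
    return allocation / total * 100.0


_SCALE = {Scaling.per_100k_population: 100_000, Scaling.per_million_population: 1_000_000}
_UNIT = {
    Scaling.none: "flag",
    Scaling.per_100k_population: "per 100,000 population",
    Scaling.per_million_population: "per 1,000,000 population",
    Scaling.percent_of_total_budget: "% of total health budget",
}


def actual_score(
    indicator: IndicatorSpec,
    obs: RawObservation,
    *,
    missing: MissingMode = "strict",
) -> ActualScore:
    """Compute one indicator's actual score from an observation.

    In strict mode (default) a missing flag or count raises
    :class:`MissingDataError`; in permissive mode a missing binary flag is
    scored 0 with a logged warning — the survey convention that structures
    without documented evidence are treated as absent.
    """
    unit = _UNIT[indicator.scaling]
    if indicator.kind is IndicatorKind.binary:
        flag = obs.binary_flags.get(indicator.id)
        if flag is None:
            if missing == "strict":
                raise MissingDataError(
                    f"missing flag for indicator '{indicator.id}' in {obs.country} {obs.year}",
                    indicator_id=indicator.id,
                    country=obs.country,
                )
            log.warning(
                "missing flag '%s' for %s %s scored as 0 (permissive mode)",
                indicator.id, obs.country, obs.year,
            )
            flag = 0
        return ActualScore(indicator.id, float(flag), unit)
    if indicator.scaling in _SCALE:
        if indicator.id not in obs.counts:
            raise MissingDataError(
                f"missing count for indicator '{indicator.id}' in {obs.country} {obs.year}",
                indicator_id=indicator.id,
                country=obs.country,
            )
        value = rate_per_population(
            obs.counts[indicator.id], obs.population, _SCALE[indicator.scaling]
        )
        return ActualScore(indicator.id, value, unit)
    if indicator.scaling is Scaling.percent_of_total_budget:
        return ActualScore(
            indicator.id,
            budget_share_percent(obs.r4h_budget, obs.total_health_budget),
            unit,
        )
    raise DomainError(
        f"indicator '{indicator.id}': continuous indicator without a scaling rule"
    )


def _required_columns(schema: BarometerSchema) -> dict[str, str]:
    """Map indicator-valued column name -> 'flag' | 'count'."""
    cols: dict[str, str] = {}
    for ind in schema.ordered_indicators():
        if ind.kind is IndicatorKind.binary:
            cols[ind.id] = "flag"
        elif ind.scaling in _SCALE:
            cols[ind.id] = "count"
        # budget-share indicators read the r4h_budget / total_health_budget
        # base columns, so they contribute no column of their own
    return cols


def read_observations(
    path: str | Path, schema: BarometerSchema, *, strict: bool = True
) -> list[RawObservation]:
    """Read a CSV observation table (one row per country-year).

    Columns are ``country, year, population, r4h_budget,
    total_health_budget`` followed by one column per flag/count indicator,
    named by indicator id (see ``data/observation_columns.md``). Unknown
    columns raise :class:`UnknownColumnError` in strict mode and are
    dropped with a warning otherwise. Blank flag cells are read as missing.
    """
    df = pd.read_csv(path, dtype={"country": str})
    missing_base = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing_base:
        raise UnknownColumnError(
            f"{path}: missing required column(s) {missing_base}", column=missing_base[0]
        )
    indicator_cols = _required_columns(schema)
    for col in df.columns:
        if col in BASE_COLUMNS or col in indicator_cols:
            continue
        if strict:
            raise UnknownColumnError(
                f"{path}: unknown indicator column '{col}'", column=col
            )
        log.warning("ignoring unknown column '%s' in %s", col, path)
    observations = []
    for _, row in df.iterrows():
        flags: dict[str, Optional[int]] = {}
        counts: dict[str, int] = {}
        for col, role in indicator_cols.items():
            if col not in df.columns or pd.isna(row[col]):
                if role == "flag":
                    flags[col] = None
                continue
            if role == "flag":
                flags[col] = int(row[col])
            else:
                counts[col] = int(row[col])
        observations.append(
            RawObservation(
                country=str(row["country"]),
                year=int(row["year"]),
                population=int(row["population"]),
                r4h_budget=float(row["r4h_budget"]),
                total_health_budget=float(row["total_health_budget"]),
                binary_flags=flags,
                counts=counts,
            )
        )
    return observations


def write_observations(
    observations: list[RawObservation], schema: BarometerSchema, path: str | Path
) -> None:
    """Write observations in the same CSV layout :func:`read_observations` reads."""
    indicator_cols = _required_columns(schema)
    rows = []
    for obs in observations:
        row: dict[str, object] = {
            "country": obs.country,
            "year": obs.year,
            "population": obs.population,
            "r4h_budget": obs.r4h_budget,
            "total_health_budget": obs.total_health_budget,
        }
        for col, role in indicator_cols.items():
            if role == "flag":
                row[col] = obs.binary_flags.get(col)
            else:
                row[col] = obs.counts.get(col)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(BASE_COLUMNS) + list(indicator_cols))
    atomic_write_text(path, df.to_csv(index=False))
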