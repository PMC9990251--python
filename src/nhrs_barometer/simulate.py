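"""Synthetic country cohorts with known generating parameters.

Emulates the structure of the regional NHRS questionnaire data so every
pipeline stage can be exercised end to end without external inputs:

* binary indicators are independent Bernoulli(p) draws;
* count indicators (staff, universities, publications) are Poisson with
  mean ``rate × population``, so per-capita actual scores vary
  realistically around ``rate × scale``;
* the research budget share is Gamma-distributed on the percent scale
  (mean ``budget_share_mean``, sd ``budget_share_dispersion``), then
  converted to currency against a drawn total health budget.

A single integer seed drives the generator; each country's draws come from
an independent substream keyed by ``(seed, country index)``, so enlarging
the cohort never reshuffles earlier countries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from ._util import atomic_write_text
from .errors import DomainError
from .schema import BarometerSchema, GoalpostSource, IndicatorKind, Scaling
from .scoring import RawObservation

_SCALE = {Scaling.per_100k_population: 100_000, Scaling.per_million_population: 1_000_000}

#: Probability of goalpost clamping above which the closed-form expected
#: score is flagged approximate.
CLAMP_PROB_FLAG = 1e-3


class SimulationConfig(BaseModel):
    """Generating parameters for a synthetic cohort.

    ``binary_prob`` keys are binary indicator ids; ``count_rate`` keys are
    count indicator ids, with rates in expected events per person (so a
    staff rate of 5e-5 means 5 staff per 100,000 population in
    expectation). Budget shares are percent of the total health budget;
    the total itself is population times a per-capita draw.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_countries: int = Field(gt=0)
    seed: int = Field(default=0, ge=0)
    year: int = 2020
    binary_prob: dict[str, float]
    count_rate: dict[str, float]
    population_range: tuple[int, int] = (2_000_000, 60_000_000)
    budget_share_mean: float = Field(default=0.5, ge=0, le=100)
    budget_share_dispersion: float = Field(default=0.3, ge=0)
    budget_per_capita_range: tuple[float, float] = (500.0, 20_000.0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for iid, p in self.binary_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"binary_prob['{iid}'] = {p} outside [0, 1]")
        for iid, r in self.count_rate.items():
            if r < 0:
                raise ValueError(f"count_rate['{iid}'] = {r} must be non-negative")
        for lo, hi, name in (
            (*self.population_range, "population_range"),
            (*self.budget_per_capita_range, "budget_per_capita_range"),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        return self


@dataclass(frozen=True)
class SyntheticCohort:
    """Simulated observations plus the per-country generating truth."""

    config: SimulationConfig
    observations: tuple[RawObservation, ...]
    truth: tuple[dict, ...]


@dataclass(frozen=True)
class ExpectedScore:
    """Closed-form expected overall score; ``approximate`` is set when
    goalpost clamping has non-negligible probability under the config."""

    value: float
    approximate: bool


def default_config(
    schema: BarometerSchema, n_countries: int = 50, seed: int = 0
) -> SimulationConfig:
    """A realistic regional-cohort configuration for the given schema.

    Bernoulli probabilities echo the mixed prevalence of governance
    structures across the region (common: ethics committees, NGOs;
    rare: research management forums); rates put countries in the
    interior of the continuous goalposts.
    """
    default_p = {
        "r4h_policy": 0.6,
        "r4h_legislation": 0.8,
        "r4h_strategic_plan": 0.55,
        "ethics_committee": 0.9,
        "research_focal_point": 0.75,
        "prioritized_agenda": 0.5,
        "research_programme": 0.85,
        "internet_connectivity": 0.8,
        "research_council": 0.6,
        "ngo_r4h": 0.9,
        "research_forum": 0.35,
        "knowledge_translation": 0.5,
        "budget_line": 0.7,
    }
    default_rate = {
        "staff_per_100k": 5.0 / 100_000,
        "universities_per_million": 1.0 / 1_000_000,
        "pubs_per_100k": 3.0 / 100_000,
    }
    binary_prob = {}
    count_rate = {}
    for ind in schema.ordered_indicators():
        if ind.kind is IndicatorKind.binary:
            binary_prob[ind.id] = default_p.get(ind.id, 0.5)
        elif ind.scaling in _SCALE:
            scale = _SCALE[ind.scaling]
            # default: expected actual at 40% of the goalpost span
            count_rate[ind.id] = default_rate.get(
                ind.id, 0.4 * (ind.goalpost_max - ind.goalpost_min) / scale
            )
    return SimulationConfig(
        n_countries=n_countries,
        seed=seed,
        binary_prob=binary_prob,
        count_rate=count_rate,
    )


def _country_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort of observations; fully reproducible from the seed."""
    observations = []
    truth = []
    share_mean = config.budget_share_mean
    share_sd = config.budget_share_dispersion
    for i in range(config.n_countries):
        rng = _country_rng(config.seed, i)
        lo, hi = config.population_range
        population = int(rng.integers(lo, hi + 1))
        flags = {
            iid: int(rng.random() < p) for iid, p in sorted(config.binary_prob.items())
        }
        counts = {
            iid: int(rng.poisson(rate * population))
            for iid, rate in sorted(config.count_rate.items())
        }
        if share_sd > 0 and share_mean > 0:
            shape = (share_mean / share_sd) ** 2
            scale = share_sd**2 / share_mean
            share = float(min(rng.gamma(shape, scale), 100.0))
        else:
            share = share_mean
        per_capita = float(rng.uniform(*config.budget_per_capita_range))
        total = population * per_capita
        obs = RawObservation(
            country=f"SIM{i:03d}",
            year=config.year,
            population=population,
            r4h_budget=share / 100.0 * total,
            total_health_budget=total,
            binary_flags=flags,
            counts=counts,
        )
        observations.append(obs)
        truth.append(
            {
                "country": obs.country,
                "population": population,
                "budget_share_pct": share,
                "binary_prob": dict(sorted(config.binary_prob.items())),
                "count_rate": dict(sorted(config.count_rate.items())),
            }
        )
    return SyntheticCohort(config, tuple(observations), tuple(truth))


def _clamp_probability(config: SimulationConfig, schema: BarometerSchema) -> float:
    """Upper bound on the per-indicator probability of index clamping."""
    worst = 0.0
    pop_lo, _ = config.population_range
    for ind in schema.ordered_indicators():
        if ind.scaling in _SCALE:
            rate = config.count_rate.get(ind.id, 0.0)
            mu = rate * pop_lo  # smallest population has the noisiest rate
            threshold = ind.goalpost_max / _SCALE[ind.scaling] * pop_lo
            worst = max(worst, float(stats.poisson.sf(math.floor(threshold), mu)))
        elif ind.scaling is Scaling.percent_of_total_budget:
            m, sd = config.budget_share_mean, config.budget_share_dispersion
            if sd > 0 and m > 0:
                shape = (m / sd) ** 2
                worst = max(
                    worst, float(stats.gamma.sf(ind.goalpost_max, shape, scale=sd**2 / m))
                )
            elif m > ind.goalpost_max:
                worst = 1.0
    return worst


def expected_overall_score(
    config: SimulationConfig, schema: BarometerSchema
) -> ExpectedScore:
    """Analytic expectation of the overall score under the generating model.

    By linearity, the expected overall score is the mean over indicators of
    the expected index: ``p`` for a Bernoulli flag and
    ``(E[actual] - min) / (max - min)`` for an unclamped continuous
    indicator. Exact only when clamping is negligible; the result carries
    an ``approximate`` flag otherwise.
    """
    expected_indices = []
    for ind in schema.ordered_indicators():
        span = ind.goalpost_max - ind.goalpost_min
        if ind.kind is IndicatorKind.binary:
            if ind.id not in config.binary_prob:
                raise DomainError(f"config lacks binary_prob for '{ind.id}'")
            expected_indices.append(config.binary_prob[ind.id])
        elif ind.scaling in _SCALE:
            if ind.id not in config.count_rate:
                raise DomainError(f"config lacks count_rate for '{ind.id}'")
            e_actual = config.count_rate[ind.id] * _SCALE[ind.scaling]
            expected_indices.append((e_actual - ind.goalpost_min) / span)
        elif ind.scaling is Scaling.percent_of_total_budget:
            expected_indices.append((config.budget_share_mean - ind.goalpost_min) / span)
    value = sum(expected_indices) / len(expected_indices) * 100.0
    approximate = _clamp_probability(config, schema) > CLAMP_PROB_FLAG
    return ExpectedScore(value=value, approximate=approximate)


def truth_json(cohort: SyntheticCohort) -> str:
    """Serialise the generating parameters as a JSON sidecar."""
    payload = {
        "config": json.loads(cohort.config.model_dump_json()),
        "countries": list(cohort.truth),
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def write_truth(cohort: SyntheticCohort, path) -> None:
    atomic_write_text(path, truth_json(cohort))
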