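"""Barometer structure: functions, sub-function indicators, and goalposts.

The African NHRS barometer organises a national health research system
(NHRS) into four functions — leadership & governance, developing &
sustaining resources, producing & utilizing research, and financing — with
17 sub-function indicators in total. Each indicator is either *binary*
(existence of a policy, law, committee, ...) or *continuous* (a per-capita
rate or a budget share), and is normalised against a pair of goalposts
(min/max reference values). Goalposts come from three kinds of sources:

``fixed``
    structural constants (0/1 for binaries, 0–100 for the staffing rate);
``cohort_max``
    the highest actual score observed across a country cohort — e.g. the
    university-density goalpost 5.39 (Cabo Verde) and the publication-rate
    goalpost 12.514 (South Africa) from the 2018 African Region survey;
``policy_target``
    a normative target — the regional commitment to devote 2% of the
    health budget to research for health.

This module defines the schema types (pydantic, strict mode: unknown fields
in hand-edited config files are rejected), the canonical default schema,
JSON/YAML (de)serialisation, and structural validation.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Optional

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import SchemaError

SCHEMA_FORMAT_VERSION = "1.0"


class IndicatorKind(str, Enum):
    binary = "binary"
    continuous = "continuous"


class Scaling(str, Enum):
    """How a raw observation becomes the indicator's actual score."""

    none = "none"
    per_100k_population = "per_100k_population"
    per_million_population = "per_million_population"
    percent_of_total_budget = "percent_of_total_budget"


class GoalpostSource(str, Enum):
    fixed = "fixed"
    cohort_max = "cohort_max"
    policy_target = "policy_target"


class IndicatorSpec(BaseModel):
    """One sub-function of the barometer.

    ``order`` keeps the conventional 1–17 numbering as a display attribute;
    the stable identity is the machine slug ``id``, so schemas can be edited
    without renumbering.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str = Field(min_length=1)
    label: str
    function_id: str
    kind: IndicatorKind
    scaling: Scaling = Scaling.none
    goalpost_min: float = Field(ge=0)
    goalpost_max: float
    goalpost_source: GoalpostSource = GoalpostSource.fixed
    benchmark_note: Optional[str] = None
    order: int = 0


class FunctionSpec(BaseModel):
    """One of the four NHRS functions and its ordered indicator ids."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str = Field(min_length=1)
    name: str
    indicator_ids: list[str]


class BarometerSchema(BaseModel):
    """A complete barometer definition.

    Indicators are stored as an ordered list (the file format); the
    ``indicator_map`` property gives id-keyed access. Structural invariants
    (partition of indicators across functions, goalpost ordering, binary
    goalpost conventions) are checked by :func:`validate_schema` rather
    than at construction, so that invalid schemas can be represented and
    reported on.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    version: str = SCHEMA_FORMAT_VERSION
    functions: list[FunctionSpec]
    indicators: list[IndicatorSpec]

    @property
    def indicator_map(self) -> dict[str, IndicatorSpec]:
        return {ind.id: ind for ind in self.indicators}

    def __getitem__(self, indicator_id: str) -> IndicatorSpec:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def function_of(self, indicator_id: str) -> FunctionSpec:
        for fn in self.functions:
            if indicator_id in fn.indicator_ids:
                return fn
        raise KeyError(indicator_id)

    def ordered_indicators(self) -> list[IndicatorSpec]:
        """Indicators in function order, then in each function's order."""
        imap = self.indicator_map
        return [imap[i] for fn in self.functions for i in fn.indicator_ids if i in imap]


def _binary(order: int, id_: str, label: str, function_id: str) -> IndicatorSpec:
    return IndicatorSpec(
        id=id_, label=label, function_id=function_id, kind=IndicatorKind.binary,
        scaling=Scaling.none, goalpost_min=0.0, goalpost_max=1.0,
        goalpost_source=GoalpostSource.fixed, order=order,
    )


def build_default_schema() -> BarometerSchema:
    """The canonical 17-indicator African NHRS barometer schema.

    Goalposts are the ones used for the 2020 Mauritius assessment: binary
    indicators 0–1; research staff per 100,000 population 0–100;
    universities conducting research for health per million population
    0–5.39 (African Region maximum, Cabo Verde); peer-reviewed publications
    per 100,000 population 0–12.514 (African Region maximum, South Africa);
    share of the health ministry budget allocated to research 0–2.0%
    (regional policy target).
    """
    A, B, C, D = "leadership_governance", "developing_resources", "producing_utilizing", "financing"
    indicators = [
        _binary(1, "r4h_policy", "Existence of a national R4H policy", A),
        _binary(2, "r4h_legislation", "Existence of a legislation/law relating to R4H", A),
        _binary(3, "r4h_strategic_plan", "Existence of a strategic R4H plan", A),
        _binary(4, "ethics_committee", "Existence of a national research ethics committee", A),
        _binary(5, "research_focal_point", "Existence of a national health research focal point/unit", A),
        _binary(6, "prioritized_agenda", "Existence of a national R4H prioritized agenda", A),
        _binary(7, "research_programme", "Existence of a health research programme/directorate at the health ministry", B),
        IndicatorSpec(
            id="staff_per_100k",
            label="Technical and support staff in the R4H programme per 100,000 population",
            function_id=B, kind=IndicatorKind.continuous,
            scaling=Scaling.per_100k_population,
            goalpost_min=0.0, goalpost_max=100.0,
            goalpost_source=GoalpostSource.fixed, order=8,
        ),
        _binary(9, "internet_connectivity", "Whether the R4H programme has internet connectivity", B),
        _binary(10, "research_council", "Presence of a national research and innovation council", B),
        IndicatorSpec(
            id="universities_per_million",
            label="Universities and colleges conducting R4H per million population",
            function_id=B, kind=IndicatorKind.continuous,
            scaling=Scaling.per_million_population,
            goalpost_min=0.0, goalpost_max=5.39,
            goalpost_source=GoalpostSource.cohort_max,
            benchmark_note="Cabo Verde, African Region 2018 survey maximum",
            order=11,
        ),
        _binary(12, "ngo_r4h", "Existence of non-governmental organization(s) undertaking R4H", B),
        _binary(13, "research_forum", "Existence of a national health research management forum", C),
        _binary(14, "knowledge_translation", "Existence of a knowledge translation platform", C),
        IndicatorSpec(
            id="pubs_per_100k",
            label="Peer-reviewed R4H publications in the 12-month window per 100,000 population",
            function_id=C, kind=IndicatorKind.continuous,
            scaling=Scaling.per_100k_population,
            goalpost_min=0.0, goalpost_max=12.514,
            goalpost_source=GoalpostSource.cohort_max,
            benchmark_note="South Africa, African Region maximum",
            order=15,
        ),
        _binary(16, "budget_line", "Presence of a funded R4H budget line within the government budget", D),
        IndicatorSpec(
            id="budget_share_pct",
            label="Percentage of the health ministry budget allocated to R4H",
            function_id=D, kind=IndicatorKind.continuous,
            scaling=Scaling.percent_of_total_budget,
            goalpost_min=0.0, goalpost_max=2.0,
            goalpost_source=GoalpostSource.policy_target,
            benchmark_note="Regional target: at least 2% of the health budget on R4H",
            order=17,
        ),
    ]
    by_fn: dict[str, list[str]] = {A: [], B: [], C: [], D: []}
    for ind in indicators:
        by_fn[ind.function_id].append(ind.id)
    functions = [
        FunctionSpec(id=A, name="Leadership and governance of R4H", indicator_ids=by_fn[A]),
        FunctionSpec(id=B, name="Developing and sustaining resources for R4H", indicator_ids=by_fn[B]),
        FunctionSpec(id=C, name="Producing and utilizing R4H", indicator_ids=by_fn[C]),
        FunctionSpec(id=D, name="Financing R4H", indicator_ids=by_fn[D]),
    ]
    return BarometerSchema(
        name="African NHRS barometer (Mauritius 2020 goalposts)",
        version=SCHEMA_FORMAT_VERSION,
        functions=functions,
        indicators=indicators,
    )


def validate_schema(schema: BarometerSchema) -> list[str]:
    """Check structural invariants; return one message per violation.

    Violations are data, not exceptions: an empty list means the schema is
    valid. Each message names the offending indicator or function.
    """
    violations: list[str] = []
    ids = [ind.id for ind in schema.indicators]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            violations.append(f"duplicate indicator id '{i}'")
        seen.add(i)
    fn_ids = [fn.id for fn in schema.functions]
    if len(fn_ids) != len(set(fn_ids)):
        violations.append("duplicate function ids")

    assigned: dict[str, str] = {}
    for fn in schema.functions:
        if not fn.indicator_ids:
            violations.append(f"function '{fn.id}' lists no indicators")
        if len(fn.indicator_ids) != len(set(fn.indicator_ids)):
            violations.append(f"function '{fn.id}' lists duplicate indicator ids")
        for iid in fn.indicator_ids:
            if iid not in seen:
                violations.append(f"function '{fn.id}' references unknown indicator '{iid}'")
            elif iid in assigned:
                violations.append(
                    f"indicator '{iid}' assigned to both '{assigned[iid]}' and '{fn.id}'"
                )
            else:
                assigned[iid] = fn.id

    for ind in schema.indicators:
        if ind.id not in assigned and ind.id in seen:
            violations.append(f"indicator '{ind.id}' belongs to no function")
        elif ind.id in assigned and assigned[ind.id] != ind.function_id:
            violations.append(
                f"indicator '{ind.id}' declares function '{ind.function_id}' but is "
                f"listed under '{assigned[ind.id]}'"
            )
        if not ind.goalpost_max > ind.goalpost_min:
            violations.append(
                f"indicator '{ind.id}': goalpost_max ({ind.goalpost_max}) must exceed "
                f"goalpost_min ({ind.goalpost_min})"
            )
        if ind.kind is IndicatorKind.binary and (
            ind.goalpost_min != 0 or ind.goalpost_max != 1 or ind.scaling is not Scaling.none
        ):
            violations.append(
                f"binary indicator '{ind.id}' must have goalposts (0, 1) and no scaling"
            )
        if ind.kind is IndicatorKind.continuous and ind.scaling is Scaling.none:
            violations.append(
                f"continuous indicator '{ind.id}' must declare a scaling rule"
            )
    return violations


def save_schema(schema: BarometerSchema, path: str | Path) -> None:
    """Write the schema as canonical JSON (stable field order, 2-space indent)."""
    from ._util import atomic_write_text

    atomic_write_text(path, schema.model_dump_json(indent=2) + "\n")


def load_schema(path: str | Path) -> BarometerSchema:
    """Read a schema from JSON (canonical) or YAML and validate it.

    Raises :class:`SchemaError` naming the failing field on parse errors and
    the offending indicator on invariant violations.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: cannot parse schema file: {exc}") from exc
    try:
        schema = BarometerSchema.model_validate(payload)
    except pydantic.ValidationError as exc:
        raise SchemaError(f"{path}: invalid schema: {exc}") from exc
    violations = validate_schema(schema)
    if violations:
        raise SchemaError(f"{path}: schema violates invariants: " + "; ".join(violations))
    return schema


def export_json_schema() -> dict:
    """JSON Schema (draft 2020-12) for the schema file format."""
    return BarometerSchema.model_json_schema()
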