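"""Deterministic evaluation of a care cascade ("filter model").

A scenario describes a population, the prevalence of a target condition,
and an ordered sequence of *filters* — stages of a care pathway (e.g.
detection, provider response, patient acceptance, treatment) through which
only a fraction of entrants pass.  The cascade is evaluated on expected
values: flows are fractional person-counts, never rounded internally, and
each filter's unit cost is charged per stage *entrant*.  The first filter's
entrants are the target group (``population_size * prevalence``); the
passers of the final filter are the *successes* (patients successfully
treated).

Rounding happens only at presentation time, via :func:`display_round`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "FilterSpec",
    "ScenarioSpec",
    "StageFlow",
    "CascadeResult",
    "OutcomeMetrics",
    "run_cascade",
    "compute_outcomes",
    "display_round",
]


class FilterSpec(BaseModel):
    """One stage of the care pathway.

    Parameters
    ----------
    name:
        Identifier, unique within a scenario.
    description:
        Free-text account of how the stage operates (e.g. "Clinician
        judgement", "Computerised short screening tool").
    pass_rate:
        Fraction of stage entrants who pass, in [0, 1].
    unit_cost:
        Non-negative cost charged for every person *entering* the stage.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str = Field(min_length=1)
    description: str = ""
    pass_rate: float = Field(ge=0.0, le=1.0)
    unit_cost: float = Field(ge=0.0)


class ScenarioSpec(BaseModel):
    """A complete cascade configuration.

    ``population_size`` is the whole population screened conceptually
    (e.g. all cancer patients); ``prevalence`` the fraction with the
    target condition (e.g. depression).  Only the target group enters
    the first filter and incurs costs.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    scenario_id: str = Field(min_length=1)
    label: str = ""
    population_size: float = Field(gt=0)
    prevalence: float = Field(ge=0.0, le=1.0)
    filters: tuple[FilterSpec, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _unique_filter_names(self) -> "ScenarioSpec":
        names = [f.name for f in self.filters]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate filter names: {dupes}")
        return self

    @property
    def target_group_size(self) -> float:
        return self.population_size * self.prevalence


@dataclass(frozen=True)
class StageFlow:
    """Expected flow through one filter: entrants, passers, stage cost."""

    filter_name: str
    entrants: float
    passers: float
    stage_cost: float


@dataclass(frozen=True)
class CascadeResult:
    """Stage-by-stage expected flows and costs for one scenario.

    All counts are unrounded expected values.  ``n_receiving_care`` is the
    number of entrants to the final (treatment) filter — those who accepted
    care; ``n_success`` is the number passing it.
    """

    scenario_id: str
    population_size: float
    prevalence: float
    target_group_size: float
    stages: tuple[StageFlow, ...]
    total_cost: float

    @property
    def n_receiving_care(self) -> float:
        return self.stages[-1].entrants

    @property
    def n_success(self) -> float:
        return self.stages[-1].passers


@dataclass(frozen=True)
class OutcomeMetrics:
    """Per-scenario cost-effectiveness summary.

    ``cost_per_patient`` divides the total pathway cost by the patients
    participating in treatment; ``cost_per_success`` divides it by the
    successfully treated.  Either ratio is ``None`` (undefined, not zero)
    when its denominator is zero.
    """

    total_cost: float
    n_receiving_care: float
    n_success: float
    cost_per_patient: Optional[float]
    cost_per_success: Optional[float]


def run_cascade(scenario: ScenarioSpec) -> CascadeResult:
    """Evaluate expected patient flow and cost through the ordered filters.

    The target group enters the first filter; each subsequent filter's
    entrants are the previous filter's passers.  Costs accrue per entrant.
    Deterministic: all flows are expected (fractional) values.
    """
    if not isinstance(scenario, ScenarioSpec):
        scenario = ScenarioSpec.model_validate(scenario)
    entrants = scenario.target_group_size
    stages = []
    total = 0.0
    for f in scenario.filters:
        passers = entrants * f.pass_rate
        cost = entrants * f.unit_cost
        stages.append(StageFlow(f.name, entrants, passers, cost))
        total += cost
        entrants = passers
    return CascadeResult(
        scenario_id=scenario.scenario_id,
        population_size=scenario.population_size,
        prevalence=scenario.prevalence,
        target_group_size=scenario.target_group_size,
        stages=tuple(stages),
        total_cost=total,
    )


def compute_outcomes(result: CascadeResult) -> OutcomeMetrics:
    """Derive cost-per-patient and cost-per-success from a cascade result.

    Ratios are computed on unrounded flows.  A zero denominator yields an
    undefined (``None``) ratio rather than zero or infinity.
    """
    cpp = result.total_cost / result.n_receiving_care if result.n_receiving_care > 0 else None
    cps = result.total_cost / result.n_success if result.n_success > 0 else None
    return OutcomeMetrics(
        total_cost=result.total_cost,
        n_receiving_care=result.n_receiving_care,
        n_success=result.n_success,
        cost_per_patient=cpp,
        cost_per_success=cps,
    )


RoundKind = Literal["count", "currency_whole", "currency_cents"]


def display_round(value: Optional[float], kind: RoundKind = "count") -> Optional[float]:
    """Round a value for display; internals always stay unrounded.

    ``count`` and ``currency_whole`` round to the nearest integer with ties
    away from zero (367.5 -> 368, 76.5 -> 77, 94.5 -> 95 — not banker's
    rounding); ``currency_cents`` rounds to 2 decimal places the same way.
    ``None`` and NaN (undefined markers) propagate unchanged.
    """
    if value is None:
        return None
    v = float(value)
    if math.isnan(v):
        return v
    if not math.isfinite(v):
        raise ValueError(f"cannot display-round non-finite value {v!r}")
    d = Decimal(repr(v))
    if kind in ("count", "currency_whole"):
        return int(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if kind == "currency_cents":
        return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    raise ValueError(f"unknown rounding kind {kind!r}")
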