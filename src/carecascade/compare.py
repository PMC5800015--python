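"""Incremental comparison of intervention scenarios against a baseline.

Implements the cost-effectiveness plane bookkeeping: incremental cost,
incremental successes, the incremental cost-effectiveness ratio (ICER =
Δcost / Δsuccesses, on unrounded increments), and the dominance quadrant
that drives policy advice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import CascadeResult, ScenarioSpec, run_cascade

__all__ = [
    "Quadrant",
    "IncrementalComparison",
    "compare",
    "policy_advice",
    "compare_all",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Bad batch-comparison setup (unknown baseline, duplicate ids)."""


class Quadrant(enum.Enum):
    """Position on the cost-effectiveness plane relative to baseline.

    Boundary convention: a scenario with identical effectiveness but higher
    cost is (weakly) dominated; identical effectiveness at lower cost is
    (weakly) dominant; a more effective scenario at identical cost is
    dominant, a less effective one dominated.  Only the exact (0, 0) point
    is EQUIVALENT.
    """

    MORE_EXPENSIVE_MORE_EFFECTIVE = "more expensive, more effective"
    MORE_EXPENSIVE_LESS_EFFECTIVE = "dominated"
    CHEAPER_MORE_EFFECTIVE = "dominant"
    CHEAPER_LESS_EFFECTIVE = "cheaper, less effective"
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class IncrementalComparison:
    """Δcost, Δsuccesses, ICER and quadrant of a scenario vs a baseline.

    ``icer`` is ``None`` exactly when ``incremental_successes`` is zero:
    division by a zero effect difference carries no decision meaning.  A
    negative ICER can occur in the off-diagonal quadrants; the quadrant is
    the primary signal there and the raw ratio is kept for transparency.
    """

    baseline_id: str
    scenario_id: str
    incremental_cost: float
    incremental_successes: float
    icer: Optional[float]
    quadrant: Quadrant


def _classify(d_cost: float, d_eff: float) -> Quadrant:
    if d_cost == 0 and d_eff == 0:
        return Quadrant.EQUIVALENT
    if d_eff > 0:
        return (
            Quadrant.MORE_EXPENSIVE_MORE_EFFECTIVE
            if d_cost > 0
            else Quadrant.CHEAPER_MORE_EFFECTIVE
        )
    if d_eff < 0:
        return (
            Quadrant.MORE_EXPENSIVE_LESS_EFFECTIVE
            if d_cost > 0
            else Quadrant.CHEAPER_LESS_EFFECTIVE
        )
    # d_eff == 0, d_cost != 0: weak dominance by cost sign
    return (
        Quadrant.MORE_EXPENSIVE_LESS_EFFECTIVE
        if d_cost > 0
        else Quadrant.CHEAPER_MORE_EFFECTIVE
    )


def compare(baseline: CascadeResult, scenario: CascadeResult) -> IncrementalComparison:
    """Compare a scenario's evaluated cascade to the baseline's.

    Increments are computed on unrounded totals and flows, and the ICER on
    unrounded increments — displayed (rounded) Δcost and Δsuccesses may
    therefore not reproduce the displayed ICER exactly; this is by design.
    """
    d_cost = scenario.total_cost - baseline.total_cost
    d_eff = scenario.n_success - baseline.n_success
    icer = d_cost / d_eff if d_eff != 0 else None
    return IncrementalComparison(
        baseline_id=baseline.scenario_id,
        scenario_id=scenario.scenario_id,
        incremental_cost=d_cost,
        incremental_successes=d_eff,
        icer=icer,
        quadrant=_classify(d_cost, d_eff),
    )


_ADVICE = {
    Quadrant.MORE_EXPENSIVE_MORE_EFFECTIVE: (
        "MORE EXPENSIVE and has BETTER EFFECTIVENESS"
    ),
    Quadrant.MORE_EXPENSIVE_LESS_EFFECTIVE: (
        "MORE EXPENSIVE and has WORSE EFFECTIVENESS (dominated by usual care)"
    ),
    Quadrant.CHEAPER_MORE_EFFECTIVE: (
        "CHEAPER and has BETTER EFFECTIVENESS (dominant over usual care)"
    ),
    Quadrant.CHEAPER_LESS_EFFECTIVE: "CHEAPER and has WORSE EFFECTIVENESS",
    Quadrant.EQUIVALENT: "EQUIVALENT in cost and effectiveness",
}


def policy_advice(comparison: IncrementalComparison) -> str:
    """Plain-language advice for the comparison's quadrant."""
    return f"Compared to usual care this scenario is {_ADVICE[comparison.quadrant]}"


def compare_all(
    scenarios: Sequence[ScenarioSpec], baseline_id: str
) -> list[IncrementalComparison]:
    """Compare every non-baseline scenario to the designated baseline.

    Input order is preserved; the baseline is not compared to itself.
    Raises :class:`ConfigurationError` on duplicate scenario ids or an
    unknown ``baseline_id``.
    """
    ids = [s.scenario_id for s in scenarios]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate scenario ids: {dupes}")
    by_id = {s.scenario_id: s for s in scenarios}
    if baseline_id not in by_id:
        raise ConfigurationError(
            f"baseline id {baseline_id!r} not among scenarios {ids}"
        )
    base = run_cascade(by_id[baseline_id])
    return [
        compare(base, run_cascade(s))
        for s in scenarios
        if s.scenario_id != baseline_id
    ]
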