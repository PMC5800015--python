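"""Deterministic sensitivity analysis for cascade scenarios.

One-way sweeps re-evaluate a scenario while varying a single parameter
(prevalence, population size, or one filter's pass rate / unit cost) over a
grid; tornado ordering ranks parameters by the span of an outcome metric
across their ranges; threshold solving inverts the model to find the
parameter value achieving a target ICER against a fixed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .compare import compare
from .model import CascadeResult, ScenarioSpec, compute_outcomes, run_cascade

__all__ = [
    "ParameterPath",
    "SweepSpec",
    "TornadoEntry",
    "one_way_sweep",
    "tornado",
    "threshold_solve",
    "SweepValidationError",
    "NoSolutionError",
    "NonMonotoneError",
]

Metric = Literal["total_cost", "n_success", "cost_per_success", "icer"]

#: validity domain of each parameter target (inclusive low, inclusive high)
_DOMAINS = {
    "prevalence": (0.0, 1.0),
    "population_size": (0.0, float("inf")),
    "pass_rate": (0.0, 1.0),
    "unit_cost": (0.0, float("inf")),
}


class SweepValidationError(ValueError):
    """Sweep range or parameter path invalid for the target field."""


class NoSolutionError(ValueError):
    """Target ICER is not achieved anywhere on the given bracket."""


class NonMonotoneError(ValueError):
    """ICER is not strictly monotone over the bracket; bisection unsafe."""


@dataclass(frozen=True)
class ParameterPath:
    """Addresses exactly one numeric field of one scenario.

    ``target`` is one of ``prevalence``, ``population_size``, ``pass_rate``
    or ``unit_cost``; the latter two require ``filter_name``.
    """

    scenario_id: str
    target: Literal["prevalence", "population_size", "pass_rate", "unit_cost"]
    filter_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.target not in _DOMAINS:
            raise SweepValidationError(f"unknown parameter target {self.target!r}")
        if self.target in ("pass_rate", "unit_cost") and not self.filter_name:
            raise SweepValidationError(
                f"target {self.target!r} requires a filter_name"
            )

    def apply(self, scenario: ScenarioSpec, value: float) -> ScenarioSpec:
        """Return a copy of ``scenario`` with only this field set to ``value``."""
        if scenario.scenario_id != self.scenario_id:
            raise SweepValidationError(
                f"parameter addresses scenario {self.scenario_id!r}, "
                f"got {scenario.scenario_id!r}"
            )
        if self.target in ("prevalence", "population_size"):
            return scenario.model_copy(update={self.target: value})
        names = [f.name for f in scenario.filters]
        if self.filter_name not in names:
            raise SweepValidationError(
                f"filter {self.filter_name!r} not in scenario "
                f"{scenario.scenario_id!r} (has {names})"
            )
        filters = tuple(
            f.model_copy(update={self.target: value}) if f.name == self.filter_name else f
            for f in scenario.filters
        )
        return scenario.model_copy(update={"filters": filters})

    def check_value(self, value: float) -> None:
        lo, hi = _DOMAINS[self.target]
        if not (lo <= value <= hi) or (self.target == "population_size" and value <= 0):
            raise SweepValidationError(
                f"value {value} outside validity domain [{lo}, {hi}] "
                f"for target {self.target!r}"
            )


@dataclass(frozen=True)
class SweepSpec:
    """Evenly spaced grid: ``steps`` points from ``low`` to ``high``."""

    low: float
    high: float
    steps: int = 11

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise SweepValidationError(
                f"sweep low ({self.low}) must be < high ({self.high})"
            )
        if self.steps < 2:
            raise SweepValidationError("sweep needs at least 2 steps")

    def grid(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.steps)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: ParameterPath
    low: float
    high: float
    metric_at_low: float
    metric_at_high: float

    @property
    def span(self) -> float:
        return abs(self.metric_at_high - self.metric_at_low)


def _metric_fn(
    metric: Metric, baseline: Optional[ScenarioSpec]
) -> Callable[[CascadeResult], Optional[float]]:
    if metric == "total_cost":
        return lambda r: r.total_cost
    if metric == "n_success":
        return lambda r: r.n_success
    if metric == "cost_per_success":
        return lambda r: compute_outcomes(r).cost_per_success
    if metric == "icer":
        if baseline is None:
            raise SweepValidationError("metric 'icer' requires a baseline scenario")
        base_result = run_cascade(baseline)
        return lambda r: compare(base_result, r).icer
    raise SweepValidationError(f"unknown metric {metric!r}")


def one_way_sweep(
    scenario: ScenarioSpec,
    baseline: Optional[ScenarioSpec],
    parameter: ParameterPath,
    sweep: SweepSpec,
    metric: Metric = "icer",
) -> list[tuple[float, Optional[float]]]:
    """Re-evaluate the scenario across a one-parameter grid.

    Exactly one field changes per evaluation.  The whole grid is validated
    against the field's domain before anything is evaluated.  For
    ``metric="icer"`` the baseline stays fixed; an undefined metric at a
    grid point (zero denominator) yields ``None`` there.
    """
    values = sweep.grid()
    for v in values:
        parameter.check_value(float(v))
    fn = _metric_fn(metric, baseline)
    return [(float(v), fn(run_cascade(parameter.apply(scenario, float(v))))) for v in values]


def tornado(
    scenario: ScenarioSpec,
    baseline: Optional[ScenarioSpec],
    parameters: Sequence[tuple[ParameterPath, float, float]],
    metric: Metric = "icer",
) -> list[TornadoEntry]:
    """Rank parameters by the span of ``metric`` across their (low, high) ranges.

    Sorted by descending span; ties broken by parameter target then filter
    name (stable).  An empty parameter list yields an empty result.
    """
    fn = _metric_fn(metric, baseline)
    entries = []
    for path, lo, hi in parameters:
        if not lo < hi:
            raise SweepValidationError(f"range low ({lo}) must be < high ({hi})")
        path.check_value(lo)
        path.check_value(hi)
        m_lo = fn(run_cascade(path.apply(scenario, lo)))
        m_hi = fn(run_cascade(path.apply(scenario, hi)))
        if m_lo is None or m_hi is None:
            raise SweepValidationError(
                f"metric {metric!r} undefined at an endpoint of "
                f"{path.target}/{path.filter_name}"
            )
        entries.append(TornadoEntry(path, lo, hi, m_lo, m_hi))
    return sorted(
        entries,
        key=lambda e: (-e.span, e.parameter.target, e.parameter.filter_name or ""),
    )


def threshold_solve(
    scenario: ScenarioSpec,
    baseline: ScenarioSpec,
    parameter: ParameterPath,
    target_icer: float,
    bracket: tuple[float, float],
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Solve for the parameter value at which the ICER equals ``target_icer``.

    Bisection on the (cheap, smooth) closed-form cascade, to absolute
    tolerance ``tol`` on the parameter.  Strict monotonicity over the
    bracket is checked at the endpoints and midpoint, not assumed — mixed
    cost structures can make the ICER non-monotone.
    """
    lo, hi = bracket
    if not lo < hi:
        raise SweepValidationError(f"bracket low ({lo}) must be < high ({hi})")
    parameter.check_value(lo)
    parameter.check_value(hi)
    base_result = run_cascade(baseline)

    def icer_at(x: float) -> float:
        c = compare(base_result, run_cascade(parameter.apply(scenario, x)))
        if c.icer is None:
            raise NoSolutionError(
                f"ICER undefined (zero incremental successes) at parameter value {x}"
            )
        return c.icer

    f_lo, f_mid, f_hi = icer_at(lo), icer_at(0.5 * (lo + hi)), icer_at(hi)
    increasing = f_lo < f_mid < f_hi
    decreasing = f_lo > f_mid > f_hi
    if not (increasing or decreasing):
        raise NonMonotoneError(
            f"ICER not strictly monotone on [{lo}, {hi}] "
            f"(endpoint/midpoint values {f_lo:.6g}, {f_mid:.6g}, {f_hi:.6g}); "
            "try a narrower bracket"
        )
    f_min, f_max = min(f_lo, f_hi), max(f_lo, f_hi)
    if target_icer == f_lo:
        return lo
    if target_icer == f_hi:
        return hi
    if not (f_min < target_icer < f_max):
        raise NoSolutionError(
            f"target ICER {target_icer} outside achieved range "
            f"[{f_min:.6g}, {f_max:.6g}] on bracket [{lo}, {hi}]"
        )

    a, b = lo, hi
    fa = f_lo - target_icer
    for _ in range(max_iter):
        m = 0.5 * (a + b)
        fm = icer_at(m) - target_icer
        if fm == 0.0 or (b - a) / 2 < tol:
            return m
        if (fa < 0) == (fm < 0):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)
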