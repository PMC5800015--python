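"""Comparison-table rendering and result export.

``render_report`` evaluates every scenario in a config, compares each to
the baseline, and produces a table with one column per scenario and the
outcome metrics as rows: total cost, cost per patient receiving care, cost
per successful outcome, incremental cost, incremental successes, ICER and
policy advice.  Every cell carries both the unrounded value and a display
string produced via ``display_round``; machine-readable exports always
retain the unrounded values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .compare import IncrementalComparison, compare, policy_advice
from .config import ModelConfig
from .model import OutcomeMetrics, compute_outcomes, display_round, run_cascade

__all__ = ["ReportTable", "render_report", "METRIC_ROWS"]

logger = logging.getLogger("carecascade")

METRIC_ROWS = (
    "total_cost",
    "cost_per_patient",
    "cost_per_success",
    "incremental_cost",
    "incremental_successes",
    "icer",
    "policy_advice",
)

_ROW_LABELS = {
    "total_cost": "Total cost",
    "cost_per_patient": "Cost per patient receiving care",
    "cost_per_success": "Cost per successful outcome",
    "incremental_cost": "Incremental total cost vs baseline",
    "incremental_successes": "Incremental successes vs baseline",
    "icer": "ICER",
    "policy_advice": "Policy advice",
}


@dataclass(frozen=True)
class ReportCell:
    raw: Union[float, str, None]
    display: str


@dataclass(frozen=True)
class ReportTable:
    """Outcome metrics per scenario: unrounded values plus display strings."""

    currency_symbol: str
    scenario_ids: tuple[str, ...]
    cells: dict  # (metric, scenario_id) -> ReportCell

    def raw_frame(self) -> pd.DataFrame:
        """Unrounded values; metrics as rows, scenarios as columns."""
        return pd.DataFrame(
            {
                sid: {m: self.cells[m, sid].raw for m in METRIC_ROWS}
                for sid in self.scenario_ids
            }
        )

    def display_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                sid: {_ROW_LABELS[m]: self.cells[m, sid].display for m in METRIC_ROWS}
                for sid in self.scenario_ids
            }
        )

    def to_text(self) -> str:
        df = self.display_frame()
        df.index.name = "Outcome metric"
        advice_label = _ROW_LABELS["policy_advice"]
        body = df.drop(index=advice_label).to_string()
        advice_lines = [
            f"  {sid}: {self.cells['policy_advice', sid].display}"
            for sid in self.scenario_ids
            if self.cells["policy_advice", sid].display != "n/a"
        ]
        if not advice_lines:
            advice_lines = ["  n/a (baseline only)"]
        return body + "\n\nPolicy advice\n" + "\n".join(advice_lines)

    def to_csv(self, path: Union[str, Path]) -> None:
        """One row per scenario x metric, unrounded value plus display string."""
        rows = [
            {
                "scenario_id": sid,
                "metric": m,
                "value": self.cells[m, sid].raw,
                "display": self.cells[m, sid].display,
            }
            for sid in self.scenario_ids
            for m in METRIC_ROWS
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        data = {
            sid: {
                m: {"value": self.cells[m, sid].raw, "display": self.cells[m, sid].display}
                for m in METRIC_ROWS
            }
            for sid in self.scenario_ids
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _currency(sym: str, value: Optional[float], cents: bool = False) -> str:
    if value is None:
        return "undefined"
    if cents:
        return f"{sym}{display_round(value, 'currency_cents'):,.2f}"
    return f"{sym}{display_round(value, 'currency_whole'):,}"


def render_report(config: ModelConfig, cents: bool = False) -> ReportTable:
    """Run all scenarios, compare to the baseline, and build the table.

    Currency cells display to whole units (ties away from zero); with
    ``cents=True`` cost-per-patient renders at 2 decimal places instead.
    The baseline's incremental cells display "n/a".
    """
    sym = config.currency_symbol
    cells: dict[tuple[str, str], ReportCell] = {}
    baseline_result = run_cascade(config.baseline)
    for spec in config.scenarios:
        result = run_cascade(spec)
        outcomes: OutcomeMetrics = compute_outcomes(result)
        logger.info(
            "scenario %s: total_cost=%.2f successes=%.4f",
            spec.scenario_id,
            result.total_cost,
            result.n_success,
        )
        sid = spec.scenario_id
        cells["total_cost", sid] = ReportCell(
            result.total_cost, _currency(sym, result.total_cost)
        )
        cells["cost_per_patient", sid] = ReportCell(
            outcomes.cost_per_patient,
            _currency(sym, outcomes.cost_per_patient, cents=cents),
        )
        cells["cost_per_success", sid] = ReportCell(
            outcomes.cost_per_success, _currency(sym, outcomes.cost_per_success)
        )
        if sid == config.baseline_id:
            for m in ("incremental_cost", "incremental_successes", "icer", "policy_advice"):
                cells[m, sid] = ReportCell(None, "n/a")
            continue
        cmp_: IncrementalComparison = compare(baseline_result, result)
        cells["incremental_cost", sid] = ReportCell(
            cmp_.incremental_cost, _currency(sym, cmp_.incremental_cost)
        )
        cells["incremental_successes", sid] = ReportCell(
            cmp_.incremental_successes,
            str(display_round(cmp_.incremental_successes, "count")),
        )
        cells["icer", sid] = ReportCell(cmp_.icer, _currency(sym, cmp_.icer))
        advice = policy_advice(cmp_)
        cells["policy_advice", sid] = ReportCell(advice, advice)
    return ReportTable(
        currency_symbol=sym,
        scenario_ids=tuple(s.scenario_id for s in config.scenarios),
        cells=cells,
    )
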