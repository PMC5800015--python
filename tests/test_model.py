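"""Cascade engine: stage flows, outcome ratios, rounding, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from carecascade import (
    FilterSpec,
    ScenarioSpec,
    compute_outcomes,
    display_round,
    generate_random_scenario,
    run_cascade,
)


def _scale_costs(spec, k):
    return spec.model_copy(
        update={
            "filters": tuple(
                f.model_copy(update={"unit_cost": f.unit_cost * k}) for f in spec.filters
            )
        }
    )


class TestRunCascade:
    def test_usual_care_stage_flows(self, baseline_result):
        """Usual care: 1500 depressed patients thin to 300/210/63/18.9."""
        r = baseline_result
        assert r.target_group_size == 1500
        assert [s.entrants for s in r.stages] == [1500, 300, 210, 63]
        assert [s.passers for s in r.stages] == pytest.approx([300, 210, 63, 18.9])
        assert [s.stage_cost for s in r.stages] == pytest.approx([7500, 1500, 0, 6300])
        assert r.total_cost == pytest.approx(15300)
        assert r.n_receiving_care == pytest.approx(63)

    def test_flows_stay_fractional_internally(self, fixture_config):
        """Improved detection: treatment stage charges $100 x 110.25 entrants."""
        r = run_cascade(fixture_config.scenario("scenario_1"))
        assert r.stages[-1].entrants == pytest.approx(110.25)
        assert r.stages[-1].stage_cost == pytest.approx(11025)
        assert r.total_cost == pytest.approx(28650)

    def test_identity_cascade(self):
        spec = ScenarioSpec(
            scenario_id="id",
            population_size=700,
            prevalence=0.2,
            filters=tuple(
                FilterSpec(name=f"f{i}", pass_rate=1.0, unit_cost=0.0) for i in range(3)
            ),
        )
        r = run_cascade(spec)
        assert r.n_success == pytest.approx(700 * 0.2)
        assert r.total_cost == 0.0

    @pytest.mark.parametrize(
        "field, value",
        [
            ("pass_rate", 1.2),
            ("pass_rate", -0.1),
            ("unit_cost", -5.0),
        ],
    )
    def test_invalid_filter_rejected_naming_field(self, field, value):
        with pytest.raises(ValidationError) as exc:
            FilterSpec(name="f", **{field: value, "pass_rate" if field != "pass_rate" else "unit_cost": 0.5})
        assert field in str(exc.value)

    def test_duplicate_filter_names_rejected(self):
        with pytest.raises(ValidationError, match="duplicate filter names"):
            ScenarioSpec(
                scenario_id="x",
                population_size=10,
                prevalence=0.5,
                filters=(
                    FilterSpec(name="a", pass_rate=0.5, unit_cost=0),
                    FilterSpec(name="a", pass_rate=0.5, unit_cost=0),
                ),
            )

    def test_empty_filters_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioSpec(scenario_id="x", population_size=10, prevalence=0.5, filters=())


class TestOutcomes:
    def test_usual_care_ratios(self, baseline_result):
        o = compute_outcomes(baseline_result)
        assert o.cost_per_patient == pytest.approx(15300 / 63)
        assert display_round(o.cost_per_patient, "currency_cents") == 242.86
        assert o.cost_per_success == pytest.approx(15300 / 18.9)
        assert display_round(o.cost_per_success, "currency_whole") == 810

    def test_expensive_treatment_ratios(self, fixture_config):
        o = compute_outcomes(run_cascade(fixture_config.scenario("scenario_4")))
        assert display_round(o.cost_per_patient, "currency_whole") == 443
        assert display_round(o.cost_per_success, "currency_whole") == 984

    def test_zero_cost_cascade(self):
        spec = ScenarioSpec(
            scenario_id="free",
            population_size=100,
            prevalence=0.5,
            filters=(FilterSpec(name="f", pass_rate=0.5, unit_cost=0.0),),
        )
        o = compute_outcomes(run_cascade(spec))
        assert o.cost_per_patient == 0.0
        assert o.cost_per_success == 0.0

    def test_zero_denominators_are_undefined_not_zero(self):
        spec = ScenarioSpec(
            scenario_id="dead-end",
            population_size=100,
            prevalence=0.5,
            filters=(
                FilterSpec(name="a", pass_rate=0.0, unit_cost=2.0),
                FilterSpec(name="b", pass_rate=0.9, unit_cost=1.0),
            ),
        )
        o = compute_outcomes(run_cascade(spec))
        assert o.cost_per_patient is None
        assert o.cost_per_success is None
        assert o.total_cost == pytest.approx(100.0)

    def test_cost_per_success_dominates_cost_per_patient(self):
        for seed in range(50):
            r = run_cascade(generate_random_scenario(seed, rate_bounds=(0.05, 1.0)))
            o = compute_outcomes(r)
            assert o.cost_per_success >= o.cost_per_patient


class TestDisplayRound:
    @pytest.mark.parametrize(
        "value, kind, expected",
        [
            (367.5, "count", 368),
            (76.5, "count", 77),
            (94.5, "count", 95),
            (18.9, "count", 19),
            (0, "count", 0),
            (-2.5, "count", -3),
            (809.5238095238095, "currency_whole", 810),
            (1333.3333333333333, "currency_whole", 1333),
            (242.85714285714286, "currency_cents", 242.86),
            (0.005, "currency_cents", 0.01),
        ],
    )
    def test_ties_away_from_zero(self, value, kind, expected):
        assert display_round(value, kind) == expected

    def test_undefined_markers_propagate(self):
        assert display_round(None, "count") is None
        assert math.isnan(display_round(float("nan"), "currency_whole"))


class TestCascadeInvariants:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_flow_conservation_and_closed_form(self, seed):
        spec = generate_random_scenario(seed)
        r = run_cascade(spec)
        assert r.stages[0].entrants == pytest.approx(spec.target_group_size)
        for prev, nxt in zip(r.stages, r.stages[1:]):
            assert nxt.entrants == prev.passers
        for s in r.stages:
            assert 0 <= s.passers <= s.entrants
        closed = spec.target_group_size * math.prod(f.pass_rate for f in spec.filters)
        assert r.n_success == pytest.approx(closed, rel=1e-9)
        assert r.total_cost == pytest.approx(sum(s.stage_cost for s in r.stages))

    @given(seed=st.integers(0, 2**31 - 1), k=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cost_linearity(self, seed, k):
        spec = generate_random_scenario(seed)
        r1, r2 = run_cascade(spec), run_cascade(_scale_costs(spec, k))
        assert r2.total_cost == pytest.approx(r1.total_cost * k)
        assert [s.passers for s in r2.stages] == [s.passers for s in r1.stages]

    @given(seed=st.integers(0, 2**31 - 1), k=st.floats(0.5, 20.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_equivariance(self, seed, k):
        spec = generate_random_scenario(seed, rate_bounds=(0.05, 1.0), cost_bounds=(1.0, 100.0))
        big = spec.model_copy(update={"population_size": spec.population_size * k})
        r1, r2 = run_cascade(spec), run_cascade(big)
        assert r2.total_cost == pytest.approx(r1.total_cost * k)
        assert r2.n_success == pytest.approx(r1.n_success * k)
        o1, o2 = compute_outcomes(r1), compute_outcomes(r2)
        assert o2.cost_per_patient == pytest.approx(o1.cost_per_patient)
        assert o2.cost_per_success == pytest.approx(o1.cost_per_success)

    def test_last_filter_pass_rate_does_not_change_cost(self, baseline):
        """Costs are charged per entrant, so the final rate moves only successes."""
        bumped = baseline.model_copy(
            update={
                "filters": baseline.filters[:-1]
                + (baseline.filters[-1].model_copy(update={"pass_rate": 0.45}),)
            }
        )
        r0, r1 = run_cascade(baseline), run_cascade(bumped)
        assert r1.total_cost == r0.total_cost
        assert r1.n_success == pytest.approx(28.35)


def test_monte_carlo_micro_simulation_agrees(baseline):
    """Independent per-person pass/fail draws reproduce the expected-value
    cascade: stage counts and per-person cost within 3 standard errors."""
    n = 100_000
    rng = np.random.default_rng(20260922)
    alive = np.ones(n, dtype=bool)
    cost = np.zeros(n)
    sim_entrants = []
    for f in baseline.filters:
        sim_entrants.append(alive.sum())
        cost[alive] += f.unit_cost
        alive &= rng.random(n) < f.pass_rate
    r = run_cascade(baseline)
    scale = baseline.target_group_size / n
    for f, sim_n, stage in zip(baseline.filters, sim_entrants, r.stages):
        p = stage.entrants / baseline.target_group_size
        se = math.sqrt(p * (1 - p) * n) if 0 < p < 1 else 0.0
        assert abs(sim_n - stage.entrants / scale) <= 3 * se + 1e-9
    p_success = r.n_success / baseline.target_group_size
    se_succ = math.sqrt(p_success * (1 - p_success) * n)
    assert abs(alive.sum() - r.n_success / scale) <= 3 * se_succ
    mean_cost = r.total_cost / baseline.target_group_size
    se_cost = cost.std(ddof=1) / math.sqrt(n)
    assert abs(cost.mean() - mean_cost) <= 3 * se_cost
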