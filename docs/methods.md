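# Methods

## Model

The package implements a deterministic expected-value cascade. A scenario
is a population size *N* > 0, a prevalence *π* ∈ [0, 1] of the target
condition, and an ordered list of *k* ≥ 1 filters, each with a pass rate
*pⱼ* ∈ [0, 1] and a per-entrant unit cost *cⱼ* ≥ 0. Only the target group
*N·π* enters the first filter; each filter's passers are the next filter's
entrants. All flows are expected values and remain fractional internally —
e.g. 110.25 entrants to a treatment stage are charged 110.25 × $100 —
because the downstream metrics (cost per success, ICER) are only internally
consistent on unrounded flows. Rounding is strictly a presentation concern.

Key modelling assumptions, inherited from the filter-model framing:

- **Filters are independent.** A change at one stage does not alter the
  pass rates of others. In reality a different treatment offer may change
  patient acceptance; such interactions are out of scope and should be
  expressed as distinct scenarios instead.
- **Costs are direct, per-entrant and homogeneous.** Every person entering
  a stage incurs that stage's unit cost, regardless of whether they pass.
  Indirect and downstream costs (untreated depression, false-positive
  workups, avoided hospitalisations) are not modelled; totals are the
  direct system cost of running the pathway, not whole-of-system cost.
- **The final filter defines success** (by convention the treatment stage;
  its entrants are the "patients receiving care", the denominator of cost
  per patient).
- Currency is an opaque unit (symbol configurable); no discounting or
  inflation adjustment — the model is single-period.

## Comparative analysis

Each scenario is compared to a designated baseline: ΔC (incremental total
cost), ΔE (incremental successes, unrounded), ICER = ΔC/ΔE, and a quadrant
on the cost-effectiveness plane. The ICER is undefined (`None`) exactly
when ΔE = 0: division by a zero effect difference has no decision meaning,
so such comparisons carry the quadrant (by cost sign) as the only signal.
Negative ICERs can occur in off-diagonal quadrants; the quadrant label is
the primary signal there and the raw ratio is retained for transparency.

Boundary convention on the sign grid: only (ΔC, ΔE) = (0, 0) is
EQUIVALENT; ΔE = 0 with ΔC > 0 is classified as (weakly) dominated and
ΔE = 0 with ΔC < 0 as (weakly) dominant; ΔE ≠ 0 with ΔC = 0 likewise falls
to the dominant/dominated side. This makes the classification exhaustive
and mutually exclusive over all nine sign combinations.

Because the ICER is computed on unrounded increments while displayed
increments are rounded independently, displayed ΔC / displayed ΔE may not
reproduce the displayed ICER (e.g. $13,350 / 14 ≈ $954 while the true ICER
on ΔE = 14.175 is $942). This is deliberate and documented rather than
"fixed": rounding before dividing would bias the headline ratio.

## Rounding

Display rounding uses ties-away-from-zero at the unit (counts, whole
currency) or at cents. The worked example pins this down: 367.5 → 368,
76.5 → 77 and 94.5 → 95 rule out banker's rounding. Implemented with
`decimal` quantisation (`ROUND_HALF_UP`) on `repr`-exact decimals, so
floating representation noise cannot flip a tie. Undefined values (`None`,
NaN) propagate unchanged; machine-readable exports always carry the
unrounded value alongside the display string.

## Worked-example fixture

The built-in fixture is the depression-in-cancer example: 10,000 cancer
patients, 15% depressed (target group 1,500), filters
detection 20% @ $5 → provider response 70% @ $5 → patient acceptance
30% @ $0 → treatment 30% @ $100, plus four scenarios each raising exactly
one filter's pass rate by 15 percentage points at a higher unit cost
(35% @ $10, 85% @ $10, 45% @ $7.50, 45% @ $300).

Two figures printed in the published source table are arithmetically
inconsistent with its own structure, and the fixture follows the structure:

- the target-group count is printed as *n* = 55,500, impossible for 15% of
  10,000 and contradicted by every downstream flow (20% detection → 300
  requires 1,500); the fixture uses 1,500;
- scenario 2's total cost is printed as $18,110 while its filter components
  sum to $18,150 — and the printed increment ($2,850) and cost per success
  ($791) are consistent only with $18,150. The model always computes totals
  from components; $18,150 is the value the tests assert.

Both discrepancies are recorded in the fixture's `notes` field.

## Sensitivity analysis

One-way sweeps re-evaluate a scenario with exactly one field changed per
grid point (prevalence, population size, or one filter's pass rate or unit
cost); the whole grid is validated against the field's domain before any
evaluation. Filter independence makes one-way analysis the natural tool
here; multi-way variations should be expressed as distinct scenarios.
Default plausible ranges, where a caller gives none, are ±50% relative,
clipped to validity domains — the source setting names no canonical
extremes, so ranges are always caller-configurable.

Tornado entries are sorted by descending span of the chosen metric, ties
broken by parameter target then filter name (stable and documented).

`threshold_solve` inverts the model by bisection on the parameter, absolute
tolerance 1e-6, at most 200 iterations — the cascade is cheap and smooth,
so a derivative-free bracketing method is the robust choice. Strict
monotonicity of the ICER over the bracket is *checked* (endpoints plus
midpoint), not assumed: the ICER has a pole where the swept parameter
crosses the baseline's success count (ΔE = 0), and mixed cost structures
can produce genuinely non-monotone stretches. A target outside the achieved
ICER range raises an error naming that range.

## Synthetic scenarios and what the tests show

`generate_random_scenario` draws a valid scenario (1–6 filters by default,
uniform pass rates in [0, 1], unit costs in [0, 200], populations in
[100, 100,000], prevalence in [0.01, 0.5]) deterministically from a seed.
It exists to exercise *structural* invariants — flow conservation,
closed-form success counts, cost linearity, scale equivariance, the ICER
identity, serialization round trips — across a wide space of shapes,
including degenerate ones (zero pass rates, zero costs). It emulates the
arithmetic of cascades, not the epidemiology: its rates and costs are not
calibrated to any literature, so passing property tests demonstrates the
engine's correctness, not the realism of any particular scenario. Realistic
conclusions require realistic inputs, which the config layer is for.

The Monte Carlo cross-check simulates 100,000 independent target-group
members through the baseline filters (Bernoulli pass/fail per stage, unit
costs charged per entrant) and requires stage counts and mean per-person
cost to agree with the deterministic cascade within 3 standard errors —
an independent confirmation that the expected-value arithmetic matches the
individual-level process it summarises.

## Numerical notes

- Closed-form successes agree with the stagewise product to 1e-9 relative
  tolerance (pure floating multiplication; no accumulation issues at
  realistic k).
- Zero denominators (no one reaches or passes the final filter) yield
  undefined ratios, never 0 or ∞.
- Config parsing rejects unknown keys outright: a silently ignored typo in
  a pass-rate key would corrupt a decision quantity.
- Scenarios in one config may have differing filter-name sequences; this
  warns (comparisons still use the final-stage success convention) rather
  than erroring, since cross-structure comparisons can be intentional.

## Limitations

Beyond the modelling assumptions above: the model is static (no time
dimension, no capacity constraints), treats pass rates as point values
(no probabilistic sensitivity analysis or parameter distributions), and
compares each scenario only against the baseline — efficiency frontiers
and extended dominance across scenarios are out of scope.
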