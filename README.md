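# carecascade

A deterministic **care-cascade ("filter") cost-effectiveness model** for
health-policy decision support, built around the problem of depression care
in cancer settings: depression is highly prevalent among cancer patients yet
poorly detected and treated, and decision makers must choose where along the
care pathway to invest limited resources.

The model represents the pathway as an ordered sequence of *filters* —
stages through which only a fraction of entrants pass. In the depression
example the filters are:

1. **detection** of depression,
2. **provider response** to detection (offer of treatment or referral),
3. **patient acceptance** of the offer,
4. **treatment effectiveness** (patients who no longer meet diagnostic
   criteria for depression).

For a population of size *N* with target-condition prevalence *π* and
filters with pass rates *p₁ … p_k* and per-entrant unit costs *c₁ … c_k*,
flows are expected values (never rounded internally):

```
entrants₁ = N·π,   entrantsⱼ₊₁ = entrantsⱼ · pⱼ
successes = N·π · ∏ⱼ pⱼ
total cost = Σⱼ cⱼ · entrantsⱼ
```

Each intervention scenario is compared to a baseline ("usual care") via the
incremental cost ΔC, incremental successes ΔE, the **incremental
cost-effectiveness ratio** ICER = ΔC/ΔE (computed on unrounded increments),
and its dominance quadrant on the cost-effectiveness plane, which drives
plain-language policy advice. One-way deterministic sensitivity analysis
(grid sweeps, tornado ordering, and bisection threshold solving for a
target ICER) sits on top.

The engine supports any number of filters; the four-filter depression
configuration — usual care plus four scenarios each improving one filter's
pass rate by 15 percentage points at a higher unit cost — ships as the
built-in fixture (`table1_fixture()`, also `examples/table1.yaml`).

## Worked example

```sh
carecascade demo          # or: python -m carecascade.cli demo
```

prints

```
                                   baseline scenario_1 scenario_2 scenario_3 scenario_4
Outcome metric
Total cost                          $15,300    $28,650    $18,150    $20,025    $27,900
Cost per patient receiving care        $243       $260       $237       $212       $443
Cost per successful outcome            $810       $866       $791       $706       $984
Incremental total cost vs baseline      n/a    $13,350     $2,850     $4,725    $12,600
Incremental successes vs baseline       n/a         14          4          9          9
ICER                                    n/a       $942       $704       $500     $1,333

Policy advice
  scenario_1: Compared to usual care this scenario is MORE EXPENSIVE and has BETTER EFFECTIVENESS
  ...
```

Under usual care, 1,500 depressed patients (15% of 10,000) thin to 18.9
expected treatment successes at a total pathway cost of $15,300 ($810 per
success). Every improvement scenario buys extra successes at extra cost;
raising **patient acceptance** (scenario 3) is the most cost-effective
option at $500 per additional success, while buying a more effective but
far more expensive treatment (scenario 4) is the least at $1,333 — the same
9 extra successes for nearly three times the incremental spend.

The same pipeline is available programmatically:

```python
from carecascade import table1_fixture, run_cascade, compare, compute_outcomes

config = table1_fixture()
base = run_cascade(config.baseline)
s3 = run_cascade(config.scenario("scenario_3"))
c = compare(base, s3)
print(c.incremental_cost, c.incremental_successes, c.icer)
# 4725.0 9.45 500.0
```

Other CLI commands: `run --config cfg.yaml [--out results.csv]`,
`validate --config cfg.yaml`, `sweep`, and `threshold`, e.g.

```sh
carecascade threshold --config examples/table1.yaml --scenario scenario_3 \
    --param patient_acceptance.pass_rate --target-icer 500 --bracket 0.31 0.9
# 0.450000
```

Config files are YAML or JSON (schema in
`src/carecascade/config.schema.json`); unknown keys and out-of-range rates
are hard errors.

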