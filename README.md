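# iwb — integrated-wellbeing lifecycle modelling

`iwb` implements a multi-domain wellbeing model as runnable, testable code:

- **Cobb–Douglas aggregation** (`iwb.core_index`): integrated wellbeing
  `IW = Π x_i^θ_i` over named domains with positive elasticities summing to
  one, its marginal contributions, and a bounded financial-wellbeing index
  `F = (OF/(OF+s))^λ · SF^(1−λ)` built from objective wealth and a
  subjective index.
- **Per-period dynamics** (`iwb.dynamics`): logistic ageing of the physical
  decay rate, saturating health investment, the health-span threshold and
  lifespan maps, regime-dependent labour income, resource flow, a strict
  no-borrowing budget and wealth accounting.
- **Lifecycle simulation** (`iwb.lifecycle_sim`): composes the transitions
  into deterministic trajectories under allocation policies
  (constant-fraction, fixed-amount, zero-spend), with budget clipping and a
  terminal summary.
- **Allocation optimization** (`iwb.allocation_opt`): a single-period
  budget splitter that equalises marginal gains via a bracketed
  Lagrange-multiplier search (closed form `C_i = θ_i·R` under linear
  symmetric investment), plus grid search over constant-fraction policies
  and a wellbeing trade-off frontier.
- **Proposition checks** (`iwb.propositions`): numerical certification that
  (1) health spending has intertemporal option value through the income
  regime, (2) joint domain dominance implies integrated-wellbeing dominance
  exactly, and (3) the required rate of return is decreasing and convex in
  physical wellbeing, with the analytic slope `−Y′(P)/OF` verified against
  finite differences.
- **Scenario I/O and CLI** (`iwb.scenarios_io`, `iwb.cli`): strict YAML
  scenario schema, named baseline fixtures, CSV/YAML writers with lossless
  round-trips.

## CLI

```bash
# simulate a scenario under a policy; writes trajectory CSV + scenario echo
iwb simulate-cmd --config scenario.yaml --phi 0.1 --out out/

# search constant-fraction health-spend policies on a phi grid
iwb optimize --config scenario.yaml --phi-grid 0:1:21 --objective mean_IW

# trace the (terminal F, terminal P, mean IW) trade-off surface
iwb frontier --config scenario.yaml --phi-grid 0:1:21

# run all three proposition checks on the shipped fixtures
iwb verify --fixtures --out out/   # exit 0 iff every check passes
```

A scenario file looks like:

```yaml
schema: iwb-scenario/1
name: example
elasticities: {financial: 0.5, physical: 0.5}
physical: {alpha_min: 0.004, alpha_max: 0.03, tau: 0.12, t0: 75.0,
           p_bar_h: 0.3, kappa: 0.05, c0: 20.0}
spans: {h_max: 50.0, a: 1.0, t_min: 40.0, t_max: 85.0, b: 1.0}
economy: {y_max: 80.0, eta: 0.8, r: 0.03}
fin_index: {wealth_scale: 250.0, objective_weight: 0.5}
initial: {p: 0.9, of: 100.0, sf: 0.7}
start_age: 30.0
horizon: 40
```

Validation is strict: unknown keys are rejected and every violated
invariant is reported with the offending field name. The shipped fixtures
(`iwb.scenarios_io.baseline_scenarios`) realise the model's regimes:
`steady-midlife`, `threshold-straddling`, `post-healthspan` and
`symmetric-static`.

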