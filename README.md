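# cloneweight

Target-trial emulation for an early-initiation in-hospital treatment using the
clone–censor–weight design, with weighted multi-state estimation and an
ordinal proportional-odds effect summary. A synthetic hospitalized-cohort
simulator with a Monte-Carlo truth oracle is bundled for end-to-end
validation.

## The problem

Observational comparisons of "ever treated" vs "never treated" hospital
patients are biased: a patient must survive long enough to receive treatment,
so deaths shortly after admission are only ever classified as untreated
(immortal time bias), and sicker patients are more likely to be offered
treatment (confounding by indication). Both biases arise at the design stage
and cannot be fixed by adjusting the final outcome model.

## The method

The package emulates a per-protocol randomized trial with a grace period:

1. **Clone.** Every eligible patient is duplicated at admission (day 0) into a
   *treated* clone (protocol: initiate treatment within the 5-day grace
   period) and a *control* clone (protocol: do not initiate within the grace
   period). Cloning removes immortal time bias by construction: both clones
   enter follow-up at day 0, before treatment status is known.
2. **Censor.** A clone is artificially censored the day its patient's observed
   history deviates from the clone's protocol: the control clone is censored
   at the treatment day when initiation falls inside the grace period, and the
   treated clone is censored at the end of the grace period if the patient has
   not initiated by then. Patients who reach an absorbing event inside the
   grace period before initiating are protocol-compliant in both arms.
3. **Weight.** Artificial censoring is informative (it depends on the same
   covariates that drive initiation), so each arm gets its own Cox
   proportional-hazards model for the time to artificial censoring (Breslow
   tie handling, Breslow baseline) on the baseline covariates. Each clone-day
   receives the inverse of its model-predicted probability of remaining
   uncensored; weights start at exactly 1, never decrease, and are constant
   after the grace period.
4. **Estimate.** Outcomes are modeled on a five-state, forward-only hospital
   multi-state structure — ward (1, initial), ICU (2), and three absorbing
   states: in-hospital death (3), discharge home (4), discharge to another
   healthcare facility (5); seven transitions, no ICU-to-ward return. Weighted
   Nelson–Aalen estimators give the cumulative transition hazards, and the
   Aalen–Johansen product integral turns them into transition matrices and
   state-occupation probabilities per arm.
5. **Summarize.** The arms are contrasted at an evaluation day on an ordinal
   severity scale (home < ward < other facility < ICU < death) with a weighted
   cumulative (proportional-odds) logistic model; an odds ratio above 1 means
   the treated arm sits in worse categories. Confidence intervals come from a
   patient-level bootstrap of the entire pipeline (cloning, weight fitting and
   estimation are redone in every replicate).

## Worked example (library)

```python
from cloneweight import (
    CensoringWeightModel, SimulationConfig, apply_eligibility,
    bootstrap_pipeline, clone_and_censor, generate_cohort, state_occupation,
)

cohort = generate_cohort(SimulationConfig(n_patients=2000, seed=7))
eligible, exclusions = apply_eligibility(cohort)
print("eligible:", len(eligible), "| excluded:", len(cohort) - len(eligible))

clones = clone_and_censor(eligible)
print("clones:", len(clones))

model = CensoringWeightModel().fit(clones)
weights = model.transform(clones)
balance = model.balance(clones, at_day=5)
print("max SMD unweighted: %.3f | weighted: %.3f"
      % (balance["smd_unweighted"].max(), balance["smd_weighted"].max()))

for arm in ("treated", "control"):
    occ = state_occupation(clones[clones["arm"] == arm],
                           weights[weights["arm"] == arm])
    row = occ.loc[30]
    print(f"{arm:>7} day-30 occupation: " + "  ".join(
        f"{name}={row[s]:.3f}" for s, name in
        [(1, "ward"), (2, "icu"), (3, "death"), (4, "home"), (5, "hcf")]))

est = bootstrap_pipeline(cohort, B=200, seed=2024, evaluation_day=30)
print(f"day-30 proportional-odds OR: {est.odds_ratio:.3f} "
      f"(95% CI {est.ci_lower:.3f}-{est.ci_upper:.3f})")
```

Output:

```text
eligible: 1833 | excluded: 167
clones: 3666
max SMD unweighted: 0.287 | weighted: 0.033
treated day-30 occupation: ward=0.058  icu=0.024  death=0.249  home=0.419  hcf=0.249
control day-30 occupation: ward=0.077  icu=0.039  death=0.222  home=0.439  hcf=0.223
day-30 proportional-odds OR: 0.899 (95% CI 0.809-1.002)
```

The simulated default cohort has a *null* treatment effect with strongly
confounded initiation; unweighted covariate imbalance between the arms at the
end of the grace period (max standardized mean difference 0.287) is reduced to
0.033 by the censoring weights, and the bootstrap interval for the day-30 odds
ratio covers 1.

## Command-line interface

```text
Usage: cloneweight [OPTIONS] COMMAND [ARGS]...

Commands:
  effects   Weighted proportional-odds ratios with pipeline bootstrap CIs.
  emulate   Apply eligibility and cloning; write exclusion log and clone table.
  estimate  Weighted Nelson-Aalen hazards and Aalen-Johansen occupation curves.
  run-all   Simulate (when configured), emulate, weight, estimate and summarize.
  simulate  Simulate a synthetic cohort and write it as CSV.
  weights   Fit arm-specific censoring models; write weight and balance tables.
```

Stage by stage:

```bash
cloneweight simulate --out cohort.csv --n 2000 --seed 7
cloneweight emulate  --cohort cohort.csv --outdir results/
cloneweight weights  --clones results/clones.csv --outdir results/
cloneweight estimate --clones results/clones.csv \
                     --weights results/weights.csv --outdir results/
```

or everything at once from a YAML run configuration:

```bash
cloneweight run-all --config run.yaml
```

which writes a reproducible bundle (`cohort.csv`, `exclusion_log.csv`,
`clones.csv`, `weights.csv`, `balance.csv`, `cumulative_hazards.csv`,
`occupation_probabilities.csv`, `effects.csv`, `effects.txt`,
`run_meta.yaml`/`run_meta.json`). All stage seeds are derived deterministically
from the single `seed` in the configuration, so a bundle is byte-reproducible.

## Estimator classes

The fit-shaped pieces follow the scikit-learn estimator convention
(`fit`/`transform`, fitted attributes with trailing underscores, clonable via
`sklearn.base.clone`):

- `CensoringWeightModel` — arm-specific Cox censoring models and clone-day
  inverse-probability weights (`transform` returns the weight table;
  `balance` returns per-covariate standardized mean differences).
- `WeightedAalenJohansen` — weighted cumulative hazards, transition matrices
  and state-occupation curves (`occupation_`, `cumhaz_`, `transition_matrix`).
- `ProportionalOddsModel` — weighted cumulative logistic model (`coef_`,
  `odds_ratio_`, `cutpoints_`).

Thin module-level functions (`compute_weights`, `weighted_nelson_aalen`,
`aalen_johansen`, `state_occupation`, `weighted_proportional_odds`, …) wrap
the same code for script use.

## Validation

`tests/test_acceptance.py` re-derives the headline claims from scratch:
weight structure, covariate balance on n=2000, the 5-state/7-transition
structure, exact reductions of the weighted estimators to standard ones
(Nelson–Aalen, 1 − Kaplan–Meier, classical cumulative incidence),
property-based row-stochasticity of every transition matrix, a hand-worked
20-clone fixture (closed-form Cox coefficients and exact occupation
fractions), removal of immortal-time bias on null-effect cohorts against a
Monte-Carlo truth oracle with bootstrap coverage, and recovery of a known
proportional-odds effect. Run with:

```bash
pytest                      # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`docs/methods.md` documents the statistical conventions (day grid, tie rules,
censoring-model specification, weight construction) and the design decisions
behind the simulator defaults.
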