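# dynrisk

Joint modeling of longitudinal biomarker trajectories and time-to-event
outcomes for dynamic disease-risk prediction, with a simulation benchmark
and a per-feature screening pipeline for longitudinal proteomics-style
panels.

## What it does

- **Simulation** (`dynrisk.simulate`): a scenario-grid generator (variance
  level x trajectory slope x group size; 45 cells by default) producing
  two-group cohorts with evenly spaced visits and truncated-normal case
  event times after the follow-up window; a multi-feature T1D-like
  screening cohort with planted associated features; and a generator that
  samples directly from the joint-model law for recovery studies.
- **Linear mixed model** (`dynrisk.lmm`): ML estimation of the
  random-intercept/random-slope model `value ~ time + (time | subject)`
  with closed-form empirical-Bayes subject effects.
- **Shared-random-effects joint model** (`dynrisk.joint`): the LMM linked
  to a Weibull proportional-hazards submodel through a current-value
  association `alpha * m(t)`, estimated by ML with adaptive Gauss-Hermite
  quadrature; Wald test for the association; conditional-survival and
  posterior-risk computations.
- **Joint latent-class mixed model** (`dynrisk.latent_class`): latent
  subgroups with class-specific trajectories and proportional Weibull
  hazards, generalized-EM estimation, multi-start grid search, and BIC
  class-number selection.
- **Baselines** (`dynrisk.baselines`): partly conditional Cox regression on
  stacked landmark data (Efron ties, subject-clustered robust variance, via
  lifelines) and the conventional last-observed-value Cox model.
- **Dynamic prediction & evaluation** (`dynrisk.prediction`): per-subject
  conditional event risks given history up to a landmark, AUROC with
  DeLong confidence intervals, scenario evaluation at 5/10/15-year
  follow-ups against a 20-year horizon, and paired Wilcoxon method
  comparisons.
- **Screening** (`dynrisk.screening`): metadata prefilter (>= 6 peptides,
  <= 10 missing values), per-feature fits with per-method significance
  rules, Benjamini-Hochberg adjustment, AUROC prioritization at successive
  evaluation ages, cross-method consensus, and leave-one-out
  cross-validation.
- **I/O + benchmark driver** (`dynrisk.io`, `dynrisk.benchmark`,
  `dynrisk.cli`): CSV dataset directories, a resumable scenario-grid
  benchmark, and a click CLI.

## CLI

```bash
# one scenario dataset (CSV directory: measurements/subjects/features)
dynrisk simulate --seed 1 --out out/sim

# the full 45-scenario default grid
dynrisk simulate --scenario-grid --seed 1 --out out/grid

# a multi-feature screening cohort
dynrisk simulate --cohort --seed 1 --out out/cohort

# fit the joint model to a single-feature dataset
dynrisk fit --data out/sim --out out/fit

# train/test evaluation of several methods
dynrisk evaluate --train out/sim --test out/sim2 --methods jm,lcmm,pccox,cox \
    --out out/eval

# screening + consensus on a cohort
dynrisk screen --data out/cohort --methods jm,pccox --out out/screen

# leave-one-out cross-validation of selected features
dynrisk loocv --data out/cohort --features prot_0000 --method jm --out out/loo

# resumable benchmark over a (reduced) scenario grid
dynrisk benchmark --config bench.yaml --seed 1 --out out/bench
```

Method labels: `jm` (shared-random-effects joint model), `lcmm`
(latent-class mixed model), `pccox` (partly conditional Cox), `cox`
(last-value Cox baseline).

## Layout

```
src/dynrisk/        package modules (see above)
tests/              pytest suite; tests/test_acceptance.py holds the
                    acceptance criteria at their stated tolerances
scripts/acceptance.py   acceptance report generator
```
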