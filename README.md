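# sohga

Model selection for population pharmacokinetics by a single-objective,
hybrid genetic algorithm — with everything it needs built in: a
nonlinear mixed-effects estimator (FO and FOCE with interaction), a
bit-string encoding of model-building decisions, a penalized fitness, a
stepwise-covariate-modeling (SCM) comparator, and a generator for a
simulated covariate-recovery study.

## The problem

Building a population PK model means choosing a compartment structure,
deciding which subject covariates enter which parameters and through
which functional form, and picking inter-individual and residual error
structures. The conventional approach tests these decisions one at a
time (stepwise forward inclusion / backward elimination by
likelihood-ratio criteria), which can miss combinations of decisions
that only pay off jointly. A genetic algorithm searches the decision
space *jointly*: every candidate model is a bit string, where each
decision (covariate on/off + functional form, IIV on/off, residual
form, initial-estimate set) occupies a fixed slice of the string.

## The method

Each candidate model is fitted by maximum marginal likelihood (FOCE with
interaction by default) and scored with the penalized fitness

```
fitness = OBV
        + 10 × (number of covariate, IIV and residual-error parameters)
        + 400   if the minimization or the covariance step failed
        + 300   if any |off-diagonal| of the estimation correlation matrix > 0.95
        (+ 300  optionally, if the condition number > 1,000)
        + niche penalty for candidates within 4 bits of a better candidate
```

where OBV is −2 log-likelihood (up to a constant). Parents are chosen by
roulette selection on fitness scaled linearly to [0.2, 4] within a
two-standard-deviation window (outliers clamp to the extremes), mated by
a single prefix-swap crossover (0.7 expected crossover events per pair),
and mutated at 0.01 per bit. The best candidate survives unchanged
(elitism), four niches are protected to preserve diversity, and every
fifth generation a one-bit-flip downhill search refines the best model
of each niche — the "hybrid" part.

The SCM comparator implements forward inclusion / backward elimination
with χ² thresholds (3.84, 6.63, 7.88 for p = 0.05, 0.01, 0.005 at 1 df)
over the same candidate effects.

## Worked example

Simulate the built-in covariate-recovery study (200 subjects, one IV
bolus, samples at 0.25–24 h; true model: exponential BMI and CRCL
effects on CL = 0.763 L/h, exponential BSA and sex effects on
V = 1.94 L, 20 % IIV on both, combined residual error) and run both
searches:

```bash
sohga simulate --n 200 --seed 20120706 -o data.csv
cat > base.yaml <<'YAML'
structural_kind: onecpt_iv
iiv: {CL: exponential, V: exponential}
residual: combined
initial: {CL: 1.0, V: 1.0, omega_CL: 0.3, omega_V: 0.3,
          sigma_prop: 0.04, sigma_add: 0.01}
YAML
sohga scm   --data data.csv --base base.yaml --p-in 0.05 --p-out 0.01
sohga sohga --data data.csv --base base.yaml --pop-size 30 --generations 10 --seed 1
```

Both searches recover the generating pattern — BMI and CRCL on
clearance, sex on volume. The stepwise run ends with

```
final effects: V~SEX:exp_d, CL~CRCL:exp, V~WT:exp, CL~BMI:exp
final OBV: 1027.54
```

and the genetic algorithm (about 14 minutes on one CPU) with

```
evaluated 393 fits in 824.8 s
best fitness: 1107.54
best effects: CL~BMI:exp, CL~CRCL:exp, V~SEX:exp_d, V~WT:exp
```

i.e. the three detectable true effects plus one spurious size covariate
(WT proxies the harder-to-separate BSA effect on V, which neither search
identifies directly — the BSA/HT/WT/SEX block is deliberately highly
correlated). Fitting the true model to the same data returns the
generating parameters within estimation error, e.g. CL = 0.763 ± 0.028
L/h with IIV estimates near 20 %.

As a library:

```python
from sohga import (CovariateSimConfig, GAConfig, base_model_spec,
                   build_covariate_space, fit_model, run_sohga,
                   simulate_covariates, simulate_dataset)

covs = simulate_covariates(CovariateSimConfig(n_subjects=200, seed=7))
ds = simulate_dataset(covs, seed=8)
base = base_model_spec()
space = build_covariate_space(base, [
    ("CL", "BMI", ("exp",), float(covs["BMI"].median())),
    ("V", "SEX", ("exp_d",), 1.0),
])
log = run_sohga(space, ds, GAConfig(pop_size=30, generations=10, seed=1))
print(log.best_genome, log.best_fitness)
```

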