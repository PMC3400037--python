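# Methods

## Scope

`sohga` implements joint model selection for population pharmacokinetics:
a hybrid genetic algorithm (GA) over binary-encoded model-building
decisions, driven by a penalized-fitness function computed from a
built-in nonlinear mixed-effects estimator, with an automated stepwise
covariate modeling (SCM) procedure as the comparator and a simulated
covariate-recovery study as the test bed. Everything runs self-contained;
no external estimation software is involved.

## The mixed-effects model and its estimator

A subject's concentration is predicted by a linear compartment model
(closed forms; one- and two-compartment, IV bolus/infusion and
first-order oral absorption; bioavailability fixed at 1). A structural
parameter's typical value starts at a covariate-free base and is
modified *sequentially* by the listed covariate effects, using the
standard functional forms (additive, proportional, exponential,
power-law, Michaelis–Menten for continuous covariates; additive,
proportional, exponential indicator sums for categorical ones, category
1 being the reference). Because additive and multiplicative forms do not
commute, the application order is fixed by the effect list (the genome's
slot order during search) and is part of the model definition.
Inter-individual variability (IIV) is a diagonal log-normal random
effect, `P_i = TV_i · exp(η_i)`, `η ~ N(0, ω²)`; ω is stored as a
standard deviation and reported as 100·ω %. Residual error is additive
(`σ²`), proportional (`F²σ²`) or combined (`F²σ²_prop + σ²_add`);
σ's are stored as variances.

The marginal likelihood is approximated by linearization:

* **FO** — linearize around η = 0; subject marginal is Gaussian with
  mean F(0) and covariance `G Ω Gᵀ + R(0)`, `G = ∂F/∂η`.
* **FOCE-I** — find each subject's conditional mode η̂ (inner
  optimization), linearize there, and evaluate the residual variance at
  η̂ ("interaction"); the linearized residual is `y − F(η̂) + G η̂`.

The reported objective value (OBV) is −2 log L with the `n·log 2π`
term dropped (a convention borrowed from the major estimation packages;
a flag restores it). Absolute OBVs are therefore only comparable within
this package — which is all that model selection requires — and the test
suite checks the FOCE-I OBV against an adaptive Gauss–Hermite quadrature
oracle (agreement within 0.5 points on small one-η problems) and against
the exact closed form for a constant-prediction Gaussian test model
(agreement to 1e-8).

Numerics worth knowing about:

* Estimation is on a transformed scale — log for positive structural
  parameters, ω's and σ's; natural for sign-free covariate
  coefficients — with L-BFGS-B inside user-specified bounds.
* The inner mode search is a damped Newton iteration, vectorized across
  all subjects, with per-subject backtracking. For the bolus
  one-compartment kind with exponential IIV the Jacobian *and* Hessian
  of the conditional objective are closed-form (the log-concentration is
  affine in `k·t`), which makes the iteration quadratically convergent;
  other kinds use finite-difference Jacobians with Fisher-scoring
  weights. Warm starts carry η̂ across outer iterations, and each solve
  guards against poisoned warm starts by comparing with the η = 0
  start.
* Objective values beyond 1e7 are log-compressed (monotonically), so the
  line search keeps a descent signal without overflowing; non-finite
  evaluations return a large sentinel. Every numerical failure —
  overflow, singular marginal covariance, wall-clock timeout, iteration
  exhaustion — is absorbed into a non-converged `FitResult`, because the
  surrounding searches must treat crashed fits as penalized candidates,
  never as exceptions.
* The covariance step takes a finite-difference Hessian of −log L at the
  optimum on the estimation scale (central by default, relative step
  1e-3; a cheaper forward scheme is available and used inside the GA),
  maps it to the reporting scale by the delta method, and computes the
  condition number as the eigenvalue ratio of the estimation
  *correlation* matrix — the same matrix whose off-diagonals feed the
  |r| > 0.95 diagnostic, which is why it was chosen over the covariance
  matrix.
* "Converged" means: optimizer success, finite objective, and no
  parameter pinned at a bound. There is no attempt to reproduce any
  external package's convergence semantics.

## The genetic algorithm

Decisions are encoded in fixed slices of a concatenated bit string; a
slot with c options uses ceil(log₂ c) bits and decodes as the slice's
integer value modulo c. The modulo rule makes every bit pattern decode
to a valid model (no wasted codes, at the price of slightly overweighting
early options of non-power-of-two slots). Operators: single prefix-swap
crossover with the cut uniform on {1,…,L−1}, applied to a parent pair
with probability 0.7; independent per-bit mutation at 0.01; roulette
selection on fitness scaled to [0.2, 4] by a linear map fitted within a
two-standard-deviation window of the population mean (outliers clamp to
the extremes — one disastrous fitness cannot flatten selection).

Fitness = OBV + 10 per covariate/IIV/residual parameter (structural
parameters are free, so structure competes on OBV alone) + 400 once if
the minimization or covariance step failed + 300 if any off-diagonal
correlation exceeds 0.95 (skipped when no correlation matrix exists —
the 400 already covers that) + an optional 300 when the condition number
exceeds 1,000 (disabled by default) + a niche penalty. Niching is greedy
leader clustering in fitness order with a Hamming radius of 4; members
and surplus leaders beyond the four protected niches are penalized
(200 by default — the exact value used historically is unpublished, so
it is a config knob chosen to deter collapse while staying below the
400 failure penalty). Elitism reinjects the best genome unchanged. Every
fifth generation, each niche leader is refined by a one-bit-flip
downhill search (move to the best strictly improving neighbor, repeat),
under an evaluation budget. All fits are cached by genome and by
decoded-model digest, and a run is a deterministic function of (space,
dataset, config, seed).

Failed or timed-out fits enter the fitness with a large placeholder OBV
(1e6) plus the 400 penalty; the scaled-selection window then clamps them
to the minimum weight. This mirrors the historical practice of letting
estimation timeouts act as soft rejections rather than errors.

## The SCM comparator

Forward inclusion fits every remaining (parameter, covariate, form)
candidate singly and accepts the largest OBV drop that clears
χ²(1−p_in, df), df being the number of coefficients added (the
Michaelis–Menten form and multi-level categorical effects add more than
one — the published procedures quote 1-df thresholds only, so the
generalization is ours). Backward elimination removes the cheapest
included effect while its cost stays below χ²(1−p_out, df). Ties break
toward the earlier-listed candidate; failed fits never qualify and are
logged. The graphical-diagnostic criterion of manual stepwise procedures
is not automatable and is out of scope.

## The simulated covariate-recovery study

200 subjects, one IV bolus (100 mg by default — the historical dose is
unpublished; OBV differences in this linear model are essentially
dose-free), samples at 0.25, 0.5, 1, 2, 3, 6, 10, 24 h. Covariates:
BMI ~ logN(ln 26, 0.15), sex ~ Bernoulli(½) (1 = male, 2 = female),
age ~ N(40, 8), creatinine ~ logN(ln 1, 0.13), height ~ N(1.7♂/1.5♀,
0.2) truncated at 1.2 m, weight = BMI·HT², BSA = √(HT·100·WT/3600),
CRCL by Cockcroft–Gault ((140−age)·WT/(72·CR), ×0.85 for women), and
four lognormal decoys CV1–CV4. Lognormals are parameterized with the
printed mean as exp(location) and the printed SD on the log scale, which
reproduces the observed mean shift (26·e^{0.15²/2} ≈ 26.3). The height
truncation prevents non-physical weights and is our addition.

True model: CL = 0.763·exp(θ₁·BMI/medBMI)·exp(θ₂·CRCL/medCRCL)·exp(η),
V = 1.94·exp(θ₃·BSA/medBSA)·exp(θ₄·1[female])·exp(η), ω = 0.2 on both
(20 % IIV), combined error σ²_prop = 0.01, σ²_add = 0.001; baseline
half-life 1.76 h, so 24 h covers ≥3 individual half-lives for nearly
all subjects. The effect coefficients are the frozen output of
`calibrate_effect_sizes`, which grid-searches each θ until adding that
single covariate to the covariate-free model moves the OBV by 10–100
points on a seeded realization (the observed drops are ≈26, 59, 19 and
42 — deliberately staggered across the band). The sex effect is signed
*negative* (females have smaller volumes beyond what size explains);
with a positive sign it would cancel the BSA effect through the
sex→height→BSA correlation and push BSA's marginal signal below the
band, contradicting the stated design.

Negative simulated concentrations (possible through the additive error
at the 24 h sample, which sits at the assay noise floor) are truncated
at zero and kept — mimicking floor censoring; the impact on estimation
is confined to the additive error component.

What the generator does *not* emulate: real assay limits of
quantification and their reporting conventions, time-varying covariates,
dosing-history complexity (multiple doses, infusions in the study
design), model misspecification of the structural kind, and data
entry/recording artifacts. Passing the recovery tests therefore
demonstrates that the search machinery finds effects of the stated size
under a correctly specified structural model — not that it is robust to
the full messiness of clinical datasets.

## Problem sizes used in the shipped experiments

The covariate-recovery study in the test suite runs SCM at (0.05, 0.01)
with 24 candidate effects and the GA at population 30 for 10
generations, downhill every 5 generations with a budget of one sweep
(24 evaluations) per niche, FOCE-I fits capped at 1,200 objective
evaluations (the cap plays the role historically played by estimation
timeouts: hopeless candidates become penalized failures rather than
sinks of compute). The GA's per-candidate covariance step uses the
forward-difference Hessian. These sizes keep the full study around a
quarter of an hour on a single CPU while leaving the selection behavior
intact; all penalty values, rates and thresholds are the defaults
documented above.

## Known limitations

* Only diagonal Ω; no inter-occasion variability, mixture/subpopulation
  models, or three-compartment kinds.
* FO is known to be badly biased for this design (it barely senses the
  clearance covariates at 20 % IIV with a 13-half-life sampling window);
  it is provided for completeness and for the one historical use case
  that required it, not as a default.
* OBVs are not comparable with any external software's printed values
  (different constants and approximation details); only differences
  within this package are meaningful.
* The GA's wall-clock timeouts introduce machine dependence if they
  bind; the shipped configurations are sized so the deterministic
  evaluation caps bind first.
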