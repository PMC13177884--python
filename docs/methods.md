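# Methods

## The problem

In cohort studies a biomarker measured intermittently (here: log eGFR, a
kidney-function marker, in an elderly cohort) is related to the hazard of
death. Three estimators of the association are in common use, differing in
how they treat measurement error and informative dropout:

1. **Time-varying Cox regression** carries the last observed value forward
   (LOCF) as a step function and maximizes a partial likelihood on
   (start, stop] counting-process intervals. Measurement error and the step
   assumption attenuate the estimated association.
2. **Uncorrected two-stage**: a linear mixed model is fitted to the
   longitudinal data first; its subject-specific predictions at event times
   are plugged into the time-varying Cox model. Smoothing removes most
   attenuation, but stage-1 uncertainty is ignored, so standard errors are
   understated, and informative dropout still biases stage 1.
3. **Joint maximum likelihood**: longitudinal and survival submodels share
   the subject's random effects; the marginal likelihood integrates them
   out. Correctly specified, this handles both measurement error and
   dropout that depends on the latent trajectory.

`jmsim` implements a generating process in which the *latent* trajectory
drives the hazard through its current value, all three estimators from
scratch, and a harness that measures bias, CI coverage and convergence over
replicate datasets.

## Generating process

For subject i with age_i ~ N(80, 6.7²) (years; the 6.7 is an SD — a
variance reading would give an implausible 2.6-year spread) and
sex_i ~ Bernoulli(0.52) (1 = female):

- latent trajectory m_i(t) = f(t)'β + β_age·age_i + b0_i + b1_i·t, with
  f(t) = t (linear kind) or a cubic B-spline basis with three functions on
  [0, 400] weeks (no interior knots; the first Bernstein column is dropped
  so the global intercept stays identifiable);
- (b0, b1) ~ N(0, D), observations y_ij = m_i(t_ij) + ε, ε ~ N(0, σ²), at
  scheduled visits {0, 100, 200, 300, 400} weeks truncated at follow-up;
- hazard h_i(t) = exp(γ0)·φ t^(φ−1)·exp(γ_age·age_i + γ_sex·sex_i +
  α·m_i(t));
- event times by inversion: Λ_i(T) = −log U with U ~ Uniform(0,1), solved
  by Brent's method per subject (or an equivalent vectorized bisection in
  the dataset path; the two agree to 1e-6 and are cross-checked in tests);
- censoring C_i = min(U(0, 800), 400) weeks; δ_i = I(T*_i < C_i).

Defaults (weekly time scale): β0 = 5.85, β_time = −0.0007, β_age = −0.023,
D = [[0.05, 2e−5], [2e−5, 1.6e−7]], σ = 0.092, φ = 1.97, γ_age = 0.09,
γ_sex = −0.39, α = −1.07, n = 200 subjects, 200 replicates.

**The baseline scale γ0 = −15.3784** deserves comment. The covariate and
association effects contribute roughly exp(γ_age·80 + α·4.0) ≈ e^2.9 to the
hazard, and t^0.97 in weeks reaches ~4·10² by the administrative horizon,
so a pure h0(t) = φ t^(φ−1) baseline would extinguish the cohort
immediately. A Weibull fit on this time scale necessarily carries a strongly
negative intercept. Since the remaining generating quantities pin down the
event process completely once γ0 is fixed, γ0 was calibrated once by
large-sample root finding (5·10⁵ subjects) so that the base scenario yields
its defining mean of 60.6 events per 200 subjects; it is a configurable
parameter like any other.

**Spline settings ("b" scenarios).** The three spline coefficients are not
dictated by the linear fit; the defaults (−0.15, −0.05, −0.28) produce an
early-steep, late-flat decline whose total 400-week drop matches the linear
trajectory's (−0.0007 × 400 = −0.28), so linear and nonlinear scenarios are
comparable in overall signal. Random effects remain intercept + linear
slope.

**Scenario grids.** The five settings each vary one quantity: visit spacing
{20, 50, 100, 150, 200, 300} weeks; α over 7 even points in [−1.5, 0]; φ
over 5 even points in [1.6, 2.8]; β_time over {−0.05, −0.03, −0.01, −0.005,
0}; σ over {0.05, 0.092, 0.2, 0.3, 0.4, 0.5}. Grids are overridable;
endpoints are fixed by the study design, interior points are a choice.

**Seeding.** Each replicate's stream is `default_rng(config.seed + rep)`,
so any single replicate is reproducible in isolation and parallel execution
cannot change results.

## Estimators

### Linear mixed model (`lmm`)

Maximizes the exact marginal Gaussian likelihood with per-subject
covariance Z_i D Z_i' + σ² I. β is profiled out by GLS at each variance
value, so the optimizer works on four coordinates: the log-Cholesky factor
of the *time-scaled* covariance S D S (S = diag(1, t_max)) and log σ. The
time scaling keeps all four curvatures comparable; without it the
slope-variance coordinate (order 1e−7 against 5e−2) makes quasi-Newton line
searches fail. The gradient is analytic (envelope theorem), tolerance 1e−8,
max 500 iterations; σ has a floor of 1e−6 so degenerate noise-free inputs
stay well-posed. ML is the default (matching the likelihood inside the
joint model); REML is available. BLUPs D Z_i' V_i^{-1}(y_i − X_i β̂) and
their conditional covariances are retained — the latter seed the joint
model's quadrature. Subjects sharing a visit pattern are batched (V_i is
identical within a pattern), so a fit costs a handful of small dense solves
regardless of n.

### Time-varying Cox (`tvcox`)

Breslow partial likelihood over (start, stop] intervals, Newton–Raphson
with step-halving, convergence at relative log-likelihood change < 1e−9 or
score norm < 1e−6 (max 100 iterations); SEs from the inverse observed
information; 95% intervals are Wald with z = 1.959964. Ties use Breslow by
default (event times are continuous here, so ties have probability zero);
Efron is available. Counting-process construction:

- `observed_LOCF`: intervals break at the subject's own visit times; a
  measurement coinciding with the follow-up end would create a zero-length
  interval and is dropped with a warning.
- `supplied_function`: intervals break at every distinct event time before
  the subject's follow-up end; the covariate on an interval is the supplied
  prediction at the interval's endpoint. This is exactly what the partial
  likelihood needs (covariates are only read at event times).

### Two-stage (`twostage`)

Stage 1 `fit_lmm` on observed rows; stage 2 `fit_tvcox` on a
supplied-function table fed by BLUP predictions, extrapolated past a
subject's last measurement where the risk set requires. Reported SEs are
the naive stage-2 ones — no propagation, by definition of the uncorrected
method. Stage-1 failure aborts with `converged=False` (no survival fit is
possible without predictions).

### Joint ML (`jointml`)

The marginal likelihood integrates the 2-D random effects per subject with
tensor-product Gauss–Hermite quadrature, 9 nodes per dimension by default,
recentred and rescaled per subject (pseudo-adaptive: centres come from the
stage-1 conditional distribution of b given y and are held fixed during
optimization; `adaptive="full"` recentres at every evaluation — on base
data the two agree to machine precision, and 9 vs 25 nodes agree to 1e−13).
Λ_i(t) uses 15-node Gauss–Legendre on [0, T_i]; on t^(φ−1) integrands with
non-integer φ this rule is accurate to ~1e−6 relative, which bounds the
accuracy of closed-form comparisons in the tests.

Direct quasi-Newton maximization (L-BFGS-B, gtol 1e−5, max 300 iterations)
replaces the EM iteration often used for such models: the target is the
same quadrature-approximated likelihood, and gradient/Hessian diagnostics
are simpler. Three conditioning devices matter on the weekly time scale:

1. the optimizer sees γ0 through the recentred level
   g0c = γ0 + φ·log 400 + 80·γ_age + 4·α (the log cumulative hazard of a
   typical subject at the horizon) — natural-scale γ0 is almost perfectly
   collinear with φ, γ_age and α;
2. slope-related coordinates (β_time, the D Cholesky) are carried per 400
   weeks;
3. remaining anisotropy is removed by diagonal preconditioning with
   curvature estimated by central differences at the start.

Starting values come from the two-stage fit plus a biomarker-free Weibull
regression for (φ, γ0). Standard errors use a central-difference numeric
Hessian (relative step 1e−4) mapped back through the parameterization
(delta method for σ, φ, γ0). A fit is **converged** when the optimizer
succeeds, the Hessian is positive definite, and the preconditioned gradient
inf-norm is below 1e−2 (observed values at genuine optima are ~1e−5; the
slack absorbs finite-difference noise). Non-converged fits still report
estimates so unconditional summaries remain possible.

## Harness

`run_scenario` records one row per replicate × method, coding crashes as
missing rather than failing the study. `summarize` computes medians, median
bias (bias is defined on the median, as the study reports medians;
mean-based bias is also emitted), empirical SD, 95%-CI coverage,
convergence %, mean events/observations and the observation-to-event ratio
(total observations / total events). Three conditioning modes:
`converged_only` (primary; methods with fewer than 50 converged replicates
out of 200 are flagged as below the display threshold), `unconditional`,
and `all_methods_converged`. A `tvcox_truth_oracle` arm feeds the latent
trajectory itself to the Cox fit, isolating how much of the LOCF bias is
measurement error versus the step-function assumption.

## What the generator does and does not emulate

It reproduces the structure the study targets: sparse scheduled visits,
event-driven truncation (informative dropout through the shared random
effects), heavy administrative censoring, and a protective biomarker. It
does not model visit-time jitter or missed visits, left truncation,
competing risks, or serial correlation in the residuals — passing tests say
nothing about those features of real cohorts. Real eGFR data also show
heavier-tailed residuals than the Gaussian error used here.

## Numerical behaviour worth knowing

- **Finite-sample bias of joint ML at the study size.** With n = 200 and
  ~61 events against 12 parameters (~5 events/parameter), the ML estimate
  of α is inflated in magnitude: medians across replicate batches sit near
  −1.2 for a generating value of −1.07, while at n = 4000 the estimate
  lands within one SE of the truth (−0.98 ± 0.12) with every other
  component recovered. The likelihood itself matches a dense 2-D
  integration oracle to 1e−14, and the optimum is insensitive to quadrature
  order and centring, so this is a property of maximum likelihood at this
  sample size, not of the implementation. CI coverage for α stays near the
  nominal 95%.
- **Degenerate inputs.** D = 0 is a valid generating configuration and a
  reportable boundary estimate, not an error. With D = 0 and σ = 0 the
  latent value is an exact affine function of age, making α unidentifiable
  in a survival model that also includes age — comparisons in that limit
  must drop the age effect.
- **Interval construction ties.** A visit exactly at the follow-up end
  contributes a measurement (inclusive rule) but no risk interval;
  T* = C exactly counts as censored (strict inequality).

## Problem sizes used in checks

Calibration and distributional checks use 10⁴–5·10⁵ subjects. Estimator
recovery checks use the study's own 200 subjects × 200 replicates for the
generator, Cox and mixed-model quantities, and 50 replicates for the joint
model, whose fits dominate compute (≈7 s each); 50 replicates put the
Monte-Carlo SE of the median α̂ near 0.1, which is adequate to detect the
attenuation and coverage effects of interest.
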