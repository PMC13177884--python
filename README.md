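# jmsim

Simulation and estimation toolkit for studying how well common survival
estimators recover the association between a longitudinally measured
biomarker and the hazard of an event, when the biomarker is observed
sparsely and with error.

The motivating setting is a cohort of older adults whose kidney function
(log eGFR) is measured roughly every two years while mortality is tracked
continuously. The package is for biostatisticians and methods researchers
who want a controlled test bed: a generating process with a known latent
trajectory driving the hazard, plus from-scratch implementations of the
estimators being compared, so that bias, confidence-interval coverage and
convergence can be measured exactly.

## Model

Each subject carries a latent (error-free) trajectory and an event hazard
linked to its current value:

```
y_ij           = m_i(t_ij) + ε_ij,          ε ~ N(0, σ²)
m_i(t)         = β₀ + β₁ t + β₂ age_i + b₀ᵢ + b₁ᵢ t,   bᵢ ~ N(0, D)
h_i(t | b_i)   = exp(γ₀) φ t^(φ−1) exp(γ_age age_i + γ_sex sex_i + α m_i(t))
```

with time in weeks, visits at {0, 100, 200, 300, 400}, censoring
C = min(U(0,800), 400), and a cubic B-spline variant of the fixed time
trend for nonlinear scenarios. Event times are drawn by inversion,
Λ_i(T) = −log U. The parameter of interest is α, the log-hazard per unit of
the current latent biomarker (default −1.07: higher kidney function is
protective).

Three estimators of α are implemented:

| method | longitudinal treatment | known weakness |
|---|---|---|
| `tvcox` | last observation carried forward | attenuation under measurement error |
| `twostage` | mixed-model BLUP predictions plugged into the Cox fit | naive SEs, dropout bias |
| `jointml` | full joint likelihood, adaptive Gauss–Hermite over b | compute, small-sample ML bias |

## Worked example

```python
from jmsim import base_config, generate_dataset, run_two_stage, fit_joint
from jmsim.tvcox import build_counting_process, fit_tvcox

cfg = base_config(seed=42)                 # 200 subjects, base parameters
ds = generate_dataset(cfg, rep_index=0)
print(int(ds.survival["event"].sum()))     # 62 events out of 200

cox = fit_tvcox(build_counting_process(ds.longitudinal, ds.survival))
ts = run_two_stage(ds)
jm = fit_joint(ds)
```

prints, on this replicate:

```
tvcox      alpha = -0.498 (se 0.401)
two-stage  alpha = -0.569 (se 0.402)
joint ML   alpha = -0.568 (se 0.405), phi = 2.20, converged = True
```

All three underestimate |α| on this particular draw — with ~62 events the
sampling SE of α̂ is ≈ 0.4, so single replicates scatter widely; the
simulation harness exists precisely to aggregate over hundreds of them.
The generating values here are α = −1.07 and φ = 1.97.

Scenario grids and the full study loop:

```python
from jmsim.harness import run_study
run_study(["5a"], "out/", methods=("tvcox", "twostage"), n_reps=200)
```

writes `results.csv` (one row per replicate × method), `summary.csv`
(median estimate, bias, coverage, convergence rate, observation-to-event
ratio, per conditioning mode) and a seed manifest. The same is available
from a shell:

```
jmsim run --setting 5a --reps 200 --seed 1 --out out/
jmsim simulate --setting 2a --reps 10 --seed 1 --out data/
jmsim summarize --in out/ --mode unconditional
```

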