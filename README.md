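# trajmix

Growth mixture modelling of late-life trajectories of cognition, daily
functioning and social health, with a calibrated synthetic-cohort
generator for end-to-end validation.

## The scientific problem

Longitudinal ageing cohorts follow older adults over 10–15 years and
repeatedly measure global cognition (MMSE, 0–30), daily functioning (a
reverse-coded combination of basic and instrumental activities of daily
living, 0–14) and social health — indices of social participation,
connections and support on a mean-100/SD-15 scale. Population averages
hide heterogeneity: a small subgroup declines fast while the majority
stays stable, and decline in one domain may or may not travel with
decline in another. `trajmix` identifies such latent trajectory classes
and quantifies their cross-domain concordance.

The core model is a **growth mixture model** (GMM). Subject *i* with
centred baseline age *aᵢ = ageᵢ − 60* belongs to latent class *k* with
probability *π_k*, and their outcome at wave time *t* (years since
baseline) is

```
y_i(t) | k = (β₀ₖ + γ₀ₖ aᵢ) + (β₁ₖ + γ₁ₖ aᵢ) t + (β₂ₖ + γ₂ₖ aᵢ) t²
             + b₀ᵢ + b₁ᵢ t + ε_i(t)
```

with random effects *(b₀, b₁) ~ N(0, Ψₖ)* (absent, intercept-only, or
intercept+slope; shared or class-specific) and residuals
*ε ~ N(0, σ²(t))* (shared or free per wave). Every growth parameter
interacts with baseline age, so one model simultaneously describes
age-60 enrollees followed to 72 and age-90 enrollees. Constraining
Ψ = 0 (or to a shared intercept) gives latent class growth analysis
(LCGA); K = 1 gives an ordinary latent growth curve (LGCA). Estimation
is EM on the observed-entries marginal likelihood (missing-at-random
follow-up), with a two-stage random-start strategy against local optima.

Around the core model the package provides

- **`trajmix.cohort` / `trajmix.scenarios`** — a seeded simulator of
  age-stratified cohorts (fixed enrolment ages; visits every 6 years
  below age 78 and every 3 years from 78; covariate-dependent class
  membership; cross-domain class coupling with exact target odds ratios;
  monotone outcome-dependent dropout), with packaged scenarios
  calibrated to published estimates from a 2,848-person Swedish cohort
  analysis,
- **`trajmix.indices`** — construction of the five analysis outcomes
  from questionnaire-level inputs and the baseline exclusion cascade,
- **`trajmix.selection`** — AIC/BIC, relative entropy, class-size and
  posterior-probability diagnostics, a parametric bootstrap likelihood
  ratio test for K vs K−1, and the three-phase model-selection protocol
  (LGCA grid → LCGA over 2–4 classes → GMM variants),
- **`trajmix.inference`** — the maximum-likelihood three-step correction
  for covariate→class regressions, pseudo-class multiple imputation with
  Rubin's-rule pooling for cross-domain odds ratios, and the four-group
  cognition × functioning concordance profile.

## Worked example

Simulate the packaged cognition scenario (n = 2,848, two latent classes,
91%/9%) and refit it:

```python
import numpy as np
from trajmix import make_scenario, simulate_cohort, GrowthSpec, fit_growth_model
from trajmix.selection import entropy, information_criteria

cfg = make_scenario("cognition", n_subjects=2848, seed=1)
cohort = simulate_cohort(cfg)
spec = GrowthSpec(degree=2, age_interactions=True, n_classes=2,
                  random_effects="intercept_slope")
fit = fit_growth_model(cohort, "mmse", spec, n_starts=50, seed=1)
aic, bic = information_criteria(fit)
print(f"log-likelihood: {fit.loglik:.1f}   AIC: {aic:.1f}   BIC: {bic:.1f}")
print(f"entropy: {entropy(fit.posteriors):.3f}")
print(f"class shares: {np.round(100 * fit.params.pi, 1)} %")
for k, b in enumerate(fit.params.beta, start=1):
    print(f"class {k}: intercept {b[0]:.2f}, slope {b[1]:.3f}/y, quad {b[2]:.4f}, "
          f"age effects ({b[3]:.4f}, {b[4]:.4f}, {b[5]:.4f})")
```

prints (about 4 s on one CPU):

```
log-likelihood: -11686.4   AIC: 23406.8   BIC: 23508.0
entropy: 0.951
class shares: [90. 10.] %
class 1: intercept 27.78, slope -0.045/y, quad -0.0046, age effects (-0.0445, -0.0076, -0.0009)
class 2: intercept 25.72, slope -0.416/y, quad -0.0561, age effects (-0.0536, -0.0092, -0.0009)
```

Class 1 (90%) is the preserved-cognition majority; class 2 (10%) starts
lower and declines almost half an MMSE point per year. The age effect on
the majority-class intercept (−0.0445) recovers the generating value of
−0.045 MMSE points per year of baseline age, and the entropy of 0.95
indicates a clean classification. The same pipeline runs from the shell:

```bash
trajmix simulate --scenario cognition --n 2848 --seed 1 --out cohort.csv
trajmix fit --input cohort.csv --outcome mmse --classes 2 \
        --out fit.json --posteriors post.csv --seed 1
trajmix select --input cohort.csv --outcome mmse --out report.json
```

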