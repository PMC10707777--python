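# chronoprof

Chrono-nutritional profiling of 24-hour meal-contact diaries, with downstream
clinical and psychometric association models.

## The problem

Chrono-nutrition studies *when* people eat rather than what or how much.  In
severe obesity, disorganized temporal eating patterns (grazing, night eating)
track with psychological burden, so clinicians would like to classify patients
into temporal eating profiles directly from a structured 24-h dietary recall.
The recall reduces each patient to 11 binary "food contact" flags — breakfast,
lunch, dinner, plus snack and nibbling slots in the morning, afternoon,
evening and night, each with a fixed clock window (e.g. breakfast 7–8 h,
night nibbling 1–6 h).

`chronoprof` implements that analysis end to end for statisticians and
epidemiologists working with such diaries:

1. **Step functions.**  Each patient's flags are expanded into an hourly
   indicator y(t), t = 1…24, equal to 1 when hour t falls inside a flagged
   slot's window.
2. **Functional smoothing.**  y(t) is approximated by an order-2 Fourier
   series f(t) = α + Σₙ₌₁² (aₙ cos(2πnt/24) + bₙ sin(2πnt/24)) fitted by
   penalized least squares, min Σₜ (f(t) − y(t))² + λ∫(D²f)² dt, with one
   roughness weight λ for the whole cohort chosen by pooled generalized
   cross-validation.
3. **Functional clustering.**  The coefficient vectors, embedded with the
   basis Gram metric (so Euclidean distance = L² distance between curves),
   are clustered with a parsimonious Gaussian subspace mixture of the
   high-dimensional-data-clustering family, fitted by EM; the number of
   profiles K minimizes BIC = −2·loglik + m·log N.
4. **Association models.**  Median (τ = 0.5) quantile regression — pinball
   loss solved exactly as a linear program, pairs-bootstrap 95% CIs, pseudo-R²
   R1 = 1 − V_full/V_null — and binary logistic regression, both with
   backward AIC selection dropping whole factor blocks.
5. **Support stages.**  Chained-equation imputation (predictive mean
   matching + logistic draws, 50 cycles) for missing-at-random cells, and a
   descriptive battery (chi-squared / Monte-Carlo Fisher, Kruskal–Wallis,
   Wilcoxon, BMI tertiles, HOMA-IR, Friedewald LDL).

Because real per-patient diaries of this kind are not public, the package
ships a **calibrated synthetic-cohort generator**: a 4-profile mixture
(weights 80/173, 11/173, 55/173, 27/173) with per-slot Bernoulli contact
probabilities set to published count ratios, covariate marginals matching the
described cohort (68% female, median age 46, median BMI 43 kg/m²), outcome
models driven by published odds ratios and median-regression coefficients
with median-zero skewed noise, and MAR missingness at published rates.  Every
stage is therefore testable with no data download.

## Worked example

```python
import numpy as np
import chronoprof as cp
from chronoprof import cluster as cl

cohort, truth = cp.generate_cohort(cp.GeneratorConfig(n=173, seed=1))
Y = cp.contact_matrix(cohort)                      # 173 x 24 step functions

sm = cp.PenalizedFourierSmoother().fit(Y)
print(sm.summary())

Z = cl.embed_curves(sm.coefficients, sm.model.basis)
best, bic_table = cl.select_k_by_bic(Z, range(2, 7), random_state=1)
print(best.summary())
```

prints

```
Penalized Fourier smoothing (order 2, period 24 h)
  curves:        173
  lambda:        11.721  (GCV-selected)
  edf:           3.959
  pooled SSE:    570.5060
  resid. var.:   0.16455

Gaussian subspace mixture AkjBkQkDk, K = 6
  log-likelihood: 1898.439
  BIC:            -3353.695
  mixing weights: [0.023, 0.179, 0.37, 0.202, 0.173, 0.052]
  cluster sizes:  [4, 31, 64, 35, 30, 9]
  intrinsic dims: [2, 1, 3, 2, 1, 1]
```

The smoother reports the shared GCV-selected roughness λ ≈ 11.7 (about 4
effective degrees of freedom out of 5) and the pooled residual variance of the
binary indicators around their smooth fits.  The mixture summary shows the
BIC-selected partition of this synthetic cohort; see `docs/methods.md` for why
BIC tends to over-resolve profile counts on flag data whose patterns repeat
exactly across patients.  `cl.profile_contact_table(...)` then produces the
per-profile contact frequency table with per-slot association tests, and
`chronoprof.regress.backward_select` fits the outcome models, e.g.

```
hypertension ~ logistic regression,  n = 142
AIC = 154.35
             estimate   lo95   hi95    OR
(Intercept)    -3.926 -6.058 -1.794 0.020
gender[M]       0.827 -0.046  1.699 2.285
age             0.079  0.038  0.120 1.082
...
```

where the refitted male odds ratio (2.29) and the per-year age effect (1.08)
recover the generator's values (2.21 and 1.09) to sampling error.

The same pipeline is scriptable: `chronoprof generate | impute | smooth |
cluster | summarize | report` with `--seed`, `--config` and `--out-dir`.

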