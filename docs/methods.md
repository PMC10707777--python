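# Methods

This note records the models implemented in `chronoprof`, the conventions and
numerical choices behind them, what the synthetic-cohort generator does and
does not emulate, and the known limitations.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. From diary flags to step functions

A patient's 24-h recall is 11 binary meal-contact flags, each tied to a fixed
clock window: breakfast [7, 8], morning nibbling [9, 12], morning snack
[10, 11], lunch [12, 13], afternoon nibbling [14, 18], afternoon snack
[16, 17], dinner [19, 20], evening nibbling [21, 24], evening snack [21, 22],
night nibbling [1, 6], night snack [3, 4].  The hourly indicator y(t),
t = 1…24, is the union of the windows of all flagged slots: y(t) ∈ {0, 1},
never a count, even where windows overlap (a snack window may sit inside the
corresponding nibbling window).  Window endpoints are treated as inclusive on
both sides; that convention is a design choice — clock ranges do not dictate
it — and is fixed once here.  "Post-dinner" and "late-night" slot names used
in some clinical write-ups are aliases for the evening/night slots.

## 2. Penalized Fourier smoothing

Each series is approximated by an order-2 Fourier basis
φ = (1, cos ωt, sin ωt, cos 2ωt, sin 2ωt), ω = 2π/24, coefficients
γ = (α, a₁, b₁, a₂, b₂), minimizing

    Σₜ (φ(t)ᵀγ − y(t))² + λ γᵀRγ,      R[j,k] = ∫ D²φⱼ D²φₖ dt.

Conventions and numerics:

* **Full-period integrals.**  The Gram and curvature matrices are computed in
  closed form over one full period [0, 24], where the basis is orthogonal:
  W = diag(24, 12, 12, 12, 12) and R = diag(0, c₁, c₁, c₂, c₂) with
  cₙ = (2πn/24)⁴·12 (c₁ ≈ 0.05637, c₂ ≈ 0.90194).  A 23-hour integral would
  break orthogonality for no modelled reason.  Tests verify both matrices
  against composite-Simpson quadrature to 1e-8.
* **Solver.**  γ = (BᵀB + λR)⁻¹Bᵀy via Cholesky factorization; no explicit
  inverse.  On the hourly grid BᵀB happens to equal W exactly (full-period
  discrete orthogonality), so the constant α is untouched by λ and the
  harmonics shrink monotonically; effective degrees of freedom
  edf = tr(B(BᵀB + λR)⁻¹Bᵀ) run from 5 (λ=0) down to 1 (λ→∞).
* **One λ for the cohort**, chosen on a default grid of 30 log-spaced values
  in [1e-4, 1e3] by pooled GCV:
  GCV(λ) = [Σᵢ SSEᵢ(λ)/(24N)] / (1 − edf(λ)/24)², ties to the smaller λ.
* **No clipping.**  f(t) is a least-squares approximation of a binary
  indicator and may leave [0, 1]; clipping would bias downstream clustering.
  A penalized-logistic variant was deliberately not implemented: on 24 binary
  points it over-smooths and flattens the very features being clustered.

## 3. Subspace-mixture clustering

Curves are compared in the functional L² metric: z = W^{1/2}γ, so Euclidean
distances between embeddings equal ∫(fᵢ − fⱼ)² dt.  On the embeddings a
parsimonious Gaussian subspace mixture (HDDC family) is fitted by EM: cluster
k has mean μ_k, an orthonormal basis Q_k of a d_k-dimensional signal subspace
with variances a_k1 ≥ … ≥ a_kd, and isotropic residual variance b_k outside
it.  All six standard members are available — AkjBkQkDk (general, the
default), AkjBQkDk, AkBkQkDk, AkBQkDk, ABkQkDk, ABQkDk — differing in which
variance parameters are shared across clusters.

* **Dimensions** d_k ∈ [1, p−1] by the Cattell scree test (gap ≥ 0.2 × the
  largest gap) on each cluster's eigenvalues, re-evaluated each M-step.
  Because re-selecting d can lower the objective, the EM applies a
  generalized-EM guard: if the fresh d's decrease the log-likelihood, the
  previous dimensions (whose exact M-step cannot decrease it) are kept for
  that iteration.  Monotonicity is audited to 1e-8 in the tests.
* **Initialization**: 25 restarts from single-start k-means partitions,
  seeded; the best final log-likelihood wins.  Runs whose smallest cluster
  falls below one patient of responsibility mass are discarded; if every
  restart degenerates the fit errors out.
* **Floors**: a_kj and b_k are floored at 1e-6 (with a_kj ≥ b_k), tolerance
  1e-6 on |Δloglik|, at most 200 iterations.
* **Model selection**: minimize BIC = −2·loglik + m·log N with
  m = (K−1) + Kp + Σ_k d_k(p − (d_k+1)/2) + #a + #b, ties to smaller K and
  then to the more parsimonious member.  Hard labels by maximum posterior,
  ties to the lower cluster index.

### A caution about discrete diaries

With 11 binary flags there are at most 2¹¹ distinct patterns, and a cohort of
173 concentrates on a few dozen of them; identical flag patterns give exactly
identical coefficient vectors.  A Gaussian mixture's likelihood is unbounded
on such data — a component can collapse onto a duplicated point, and at a
variance floor of 1e-6 such a component contributes on the order of +30 log-
likelihood units per member.  Two consequences, both visible in this
package's own simulations:

* BIC across K is then driven by how many duplicate groups the optimizer
  isolates, not by the latent mixture structure: on synthetic cohorts drawn
  from a 4-profile mixture with *independent* within-profile flags, the
  selected K concentrates at the top of the 2–6 range, and no variance-floor
  or family choice we examined restores K = 4 (large floors merge the real
  profiles instead; the transition is abrupt).  The label agreement with the
  generating profiles (ARI ≈ 0.3) sits well below what a supervised Gaussian
  classifier achieves on the same embeddings (ARI ≈ 0.6), i.e. the
  information is present but the unsupervised likelihood surface does not
  point at it.
* Real diaries plausibly behave better: profiles derived from real cohorts
  carry within-profile dependence between slots, which concentrates each
  profile on few patterns and makes a small K genuinely optimal.  The
  generator here samples flags independently given the profile (a
  deliberately simple, documented choice), so passing or failing cluster-count
  recovery on these synthetic cohorts says little about cluster-count
  recovery on real data.  The oracle suites — exact recovery and BIC
  selection on separated continuous clusters, density agreement with a
  full-covariance Gaussian mixture, EM monotonicity — are what validate the
  clustering code itself.

The profile summary table reports count (%) of each contact per cluster
(decreasing size order) with a chi-squared test per slot, switching to
Monte-Carlo Fisher when any expected cell is below 10; slots with no
variation get no test.

## 4. Synthetic-cohort generator

The generator is the package's study-condition definition, not a tuning
surface; its defaults are fixed to the published cohort description.

* **Profiles**: categorical with weights 80/173, 11/173, 55/173, 27/173.
* **Contacts**: per-slot Bernoulli given the profile, probabilities equal to
  the exact published count ratios (e.g. Profile-1 breakfast 74/80, Profile-3
  afternoon nibbling 22/55).  Exact fractions rather than rounded
  percentages make the large-n overall prevalences reproduce the printed
  overall column identically (e.g. breakfast 154/173).  Where a narrative
  percentage and the table counts disagree, the counts win.  Slots are
  sampled independently within a profile — see the caution above.
* **Covariates** (independent of profile by default): gender F with p = 0.68;
  age from a skew-normal (location 32.479, scale 22.278, shape 21.077)
  truncated to [17, 71], calibrated offline so the truncated quartiles are
  39/46/55; BMI from a log-normal (μ = 3.746008, σ = 0.174267) truncated to
  [32.9, 80.3], calibrated so the truncated tertile cuts are 40.2/46.2
  (median 43.0, mean 44.0); education multinomial 0.42/0.43/0.15; activity
  0.17, alcohol 0.14, smoking 0.19, shift work 0.18, statins 0.10.  Only the
  quantile targets are contractual; the distribution families are the
  implementer's choice.  Smoking can optionally be made profile-dependent.
* **Outcomes**: comorbidities by logistic inverse-link on linear predictors
  whose coefficients are the logs of published odds ratios (hypertension:
  intercept log 0.01, age log 1.09, male log 2.21, alcohol log 0.34;
  dyslipidemia: intercept log 0.77, male log 11.7, activity log 2.07,
  smoking log 0.48; diabetes: intercept log 0.01, age log 1.05, male
  log 2.99, activity log 0.31, BMI-tertile logs 1.61/3.12).  Pre-diabetes is
  assigned among the non-diabetic at 0.40/0.82 so the marginal three-level
  split is ≈42/40/18%.  Continuous outcomes (HDL, TG, HOMA, TC, FPG and the
  seven psychometric totals) are linear predictors with the published
  median-regression coefficients plus noise scale·(exp(σZ) − 1), Z∼N(0,1):
  right-skewed with median exactly zero, so τ=0.5 regression — not least
  squares — recovers the coefficients.  Noise scales are set per outcome to
  give spreads of the right order; they are not calibration targets.
  Within the generator's linear predictors the BMI tertile uses the fixed
  cuts 40.2/46.2.  LDL is derived by Friedewald from TC/HDL/TG, and insulin
  is back-computed from HOMA and FPG, keeping derived-variable arithmetic
  internally consistent.  HOMA is structurally missing for insulin-treated
  patients (a quarter of the diabetic).
* **Missingness**: MAR via a logistic model in standardized age and male
  gender (slopes 0.3/0.2); the intercept is solved per column (Brent) so the
  expected marginal rate over the realized cohort equals the published rate
  (dyslipidemia 14.5%, shift work 0.6%, BIS-11 2.9%, TC 14.5%, HDL 15%,
  LDL 15%, TG 14.5%, HOMA 15%).  Because the drivers are always observed,
  masked cells are independent of their own hidden values given covariates;
  a logistic audit of the mask on the hidden value verifies this.
* True labels, linear predictors and pre-masking values are emitted in a
  separate truth table the pipeline never reads.

What the generator does **not** emulate: within-profile slot dependence,
covariate–profile dependence (beyond optional smoking), item-level
psychometrics, sleep, caloric intake, measurement error in covariates.

## 5. Chained imputation

Single-dataset MICE: initial fill by random draws from each target's observed
values (recorded as cycle 0 of the trace), targets visited in increasing
missingness order, 50 cycles by default.  Continuous targets use predictive
mean matching: β̂ by least squares on observed rows, a bootstrap refit β*
for parameter uncertainty, predictions ŷ_obs = Xβ̂ and ŷ_mis = Xβ* (type-1
matching), k = 5 nearest donors by predicted value, one donor's observed
value drawn — imputations therefore always lie in the observed support.
Binary targets use Bernoulli draws at probabilities from a bootstrap-refitted
logistic model, falling back to an L2-penalized fit under separation.  The
per-cycle mean/variance of imputed cells forms the convergence trace, meant
for graphical inspection; tests check that it stabilizes relative to the
burn-in.  One completed dataset is returned (no Rubin pooling in the default
path): the downstream profiling analysis operates on a single completed
table.  Observed cells are asserted untouched.

## 6. Association models

* **Median regression** (τ = 0.5): the pinball objective is solved exactly as
  the primal LP (β free, residual split; HiGHS), which makes the
  intercept-only fit the sample median by construction.  95% CIs by pairs
  bootstrap (B = 999, percentile); rank-inversion intervals were not
  implemented.  An independent dual-LP formulation (max yᵀν, Xᵀν = 0,
  ν ∈ [τ−1, τ]) and statsmodels QuantReg serve as cross-checks in tests,
  never as the implementation.
* **Quantile AIC** uses the asymmetric-Laplace working likelihood,
  AIC = 2p + 2n·log(mean pinball loss).  Its selection behaviour is exactly
  calibrated when the outcome noise is Laplace (where that likelihood is the
  truth) and mildly liberal/conservative otherwise, depending on the noise
  density at the median; the audit tests use Laplace noise for this reason.
* **Pseudo-R²**: R1 = 1 − V_full/V_null on summed pinball loss.
* **Logistic regression**: statsmodels maximum likelihood (IRLS), Wald 95%
  CIs, odds ratios by exponentiation; non-convergence within 100 iterations
  is an error and |β| > 15 triggers a quasi-separation warning.
* **Backward AIC selection** treats each factor as an atomic block
  (treatment coding with explicit references: Female, no-alcohol, no-smoking,
  no-activity, BMI tertile 1, middle school, Profile 1, no-comorbidity) and
  repeatedly drops the block whose removal most reduces AIC, ties to the
  earliest-declared block, stopping at no improvement; the full trace is kept.
  Psychometric-score templates additionally include hypertension, three-level
  diabetes and dyslipidemia among the candidate predictors; the comorbidity
  and metabolic templates do not.  Factor levels unobserved in the estimation
  sample are dropped from the design rather than producing zero columns.

## 7. Descriptive battery

BMI = weight/height²; HOMA-IR = insulin·FPG/22.5 (missing under insulin
therapy); Friedewald LDL = TC − HDL − TG/2.2 in mmol/L, invalid above
TG = 4.52 mmol/L (400 mg/dL); BMI tertiles at the empirical 1/3, 2/3
quantiles (or fixed cuts), intervals closed on the right.  Group tests:
Pearson chi-squared without continuity correction; Monte-Carlo Fisher for
r×c tables (tables drawn conditional on both margins by Patefield's
algorithm, p = (1 + #{X²_sim ≥ X²_obs})/(reps + 1), default 100 000 reps),
engaged automatically when any expected cell is below 10; Kruskal–Wallis
with mid-rank ties; Wilcoxon rank-sum (the two-independent-samples reading)
via the normal approximation.  Calibration tests draw varied multinomial
null tables, where the mixture of per-table discrete p-value supports is
uniform; on a single fixed margin the MC p-value is discrete and
conservative, which is expected behaviour for exact-style tests.

## 8. Problem sizes and determinism

Test and acceptance runs use the cohort size the profiling targets
(n = 173, 20 replicates), n = 100 000 for generator calibration, n = 5 000 ×
20 seeds for logistic recovery and n = 2 000 × 20 for imputation recovery —
sizes at which every suite completes in a few minutes on one CPU.  All
randomness flows through numpy Generators seeded from the run seed; fixed
(config, seed) reproduces every output byte-for-byte.

## 9. Known limitations

* Cluster-count and share recovery on the synthetic cohorts is limited by
  the duplicate-pattern degeneracy of §3; the package reports what BIC
  selects rather than forcing a profile count.
* The Monte-Carlo Fisher test is not the network-algorithm exact test;
  its p-values carry O(1/√reps) noise.
* Quantile CIs ignore within-cycle imputation uncertainty (single completed
  dataset).
* The generator's independence assumptions (slots within profile,
  covariates across each other and profiles) are simplifications; parameter
  recovery under them does not certify behaviour under real-world dependence.
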