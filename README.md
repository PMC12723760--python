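# pacctraj

Latent class mixed-effects models (LCMMs) for heterogeneous cognitive
trajectories in preclinical Alzheimer's disease.

Cognitively unimpaired older adults with elevated brain amyloid decline, on
average, on the Preclinical Alzheimer Cognitive Composite (PACC) — but the
average hides enormous heterogeneity: in A4/LEARN-like cohorts roughly
three quarters of amyloid-positive participants stay cognitively stable
over the length of a prevention trial.  This package implements, end to
end, the analysis that quantifies that heterogeneity and its consequences
for trial design:

* a **synthetic cohort generator** that emulates the A4/LEARN data
  structure — three latent trajectory classes (stable, slow decliner, fast
  decliner) with biomarker-driven multinomial-logit membership,
  class-specific natural-spline mean trajectories, subject random
  intercepts, semiannual-to-annual visits over 7 years and monotone
  dropout — so every stage is testable against known ground truth;
* **preprocessing**: Box-Cox outcome transform with maximum-likelihood λ,
  natural cubic spline time bases (df 1–3, knots at the median/tertiles of
  observation time), hippocampal atrophy residualize-and-z scores, and the
  8-region tau PET cortical composite;
* the **LCMM** itself, estimated by multi-start EM;
* **model selection** over the (classes × spline df) grid by BIC/ICL;
* **ten-fold cross-validated baseline-only class prediction** with
  precision-recall metrics;
* **class-specific clinical-trial power** under attrition, anchored to the
  "maximum possible benefit" of an amyloid-negative stable reference group;
* a **CART classification tree** characterizing the classes from baseline
  variables, with impurity-based variable importance.

## Model

For subject *i* with Box-Cox-transformed PACC vector *y<sub>i</sub>*, the
LCMM couples two submodels:

* membership: P(c<sub>i</sub> = g | x<sub>i</sub>) = π<sub>ig</sub>, a
  multinomial logit in baseline covariates (P-tau217, amyloid PET, APOE ε4,
  sex, age, education, hippocampal atrophy, treatment arm), reference =
  the stable class;
* longitudinal: within class g,
  y<sub>i</sub> = S<sub>i</sub>α<sub>g</sub> + W<sub>i</sub>γ +
  b<sub>i</sub>1 + ε<sub>i</sub>, with class-specific natural-spline time
  effects α<sub>g</sub>, shared covariate effects γ, random intercept
  b<sub>i</sub> ~ N(0, σ<sub>b</sub>²) and residuals
  ε<sub>i</sub> ~ N(0, σ<sub>e</sub>²I).

The observed likelihood is the mixture
L<sub>i</sub> = Σ<sub>g</sub> π<sub>ig</sub> φ(y<sub>i</sub>;
S<sub>i</sub>α<sub>g</sub> + W<sub>i</sub>γ, σ<sub>b</sub>²J +
σ<sub>e</sub>²I), maximized by ECM with posterior class probabilities
τ<sub>ig</sub> as the E-step.  BIC = −2ℓ + p·log N; ICL adds twice the
posterior entropy.  See `docs/methods.md` for estimation details and design
choices.

## Worked example

```bash
pacctraj run --out-dir run_demo --n 400 --seed 20260121
```

simulates a 400-subject cohort from the A4/LEARN-like preset and runs the
whole pipeline.  The printed report (abridged, from this exact command):

```
Model selection: G=3, spline df=2 (BIC 12238.6, ICL 12344.1)
Class proportions: class 1: 79.8%, class 2: 14.2%, class 3: 6.0%
Mean posterior confidence: 0.95
Cross-validated accuracy: 0.865 (95% CI 0.828-0.895)
One-vs-rest AUPRC: 0: 0.98, 1: 0.62, 2: 0.52

Trial power (by group, horizon, effect fraction):
  amyloid_positive_stable      2y f=1.0: power 0.09
  amyloid_positive_decliner    2y f=0.2: power 0.98
  ...

Tree variable importance (%):
  ptau217              58.2
  amyloid_centiloid    19.1
  ...
```

Reading this: selection recovers the generating model (three classes, two
spline degrees of freedom); the fitted class shares are close to the
generating 77/16/7 mixing; subjects are assigned to classes with high
posterior confidence (0.95); baseline-only prediction identifies stable
subjects almost perfectly (AUPRC 0.98) but decliners only partially
(0.62/0.52) — the same qualitative gap that motivates enrichment
strategies; a trial read out in decliners is far better powered than one
in stable participants; and plasma P-tau217 dominates the baseline
decision tree.

The same stages are available as numbered drivers:

```bash
python analysis/01_simulate_cohort.py --n 1629 --seed 20260121
python analysis/02_select_model.py
python analysis/03_characterize_classes.py
python analysis/04_cross_validate.py
python analysis/05_trial_power.py
python analysis/06_classification_tree.py
```

`05_trial_power.py` also evaluates the closed-form scenarios built from
the published stable-group summaries, printing the maximum-benefit effect
sizes (0.26 / 0.24 PACC points at 2 / 4 years) and the corresponding
powers (≈44% / ≈32%) for a 500-per-arm trial with 10%/20% attrition.

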