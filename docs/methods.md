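# Methods

This note documents the statistical procedures, conventions and synthetic
study conditions implemented in `ntcpval`, and the design choices made
where more than one defensible convention exists.

## The model and its evaluation

The xerostomia model is a logistic regression on two aggregated dose
features — the sum of the ipsi- and contralateral parotid mean doses, and a
single submandibular-gland (SMG) mean dose — plus an additive score for
pre-treatment xerostomia severity. The shipped `lipp.json` carries the
published coefficients (intercept −2.2951; 0.0996 / Gy parotid; 0.0182 / Gy
SMG; baseline scores 0 / 0.459 / 1.207); `lipp_recalibrated.json` carries
the published recalibrated values (−3.2132; 0.1354; 0.0247), with baseline
scores scaled by the implied slope 1.36 for internal consistency.

Two published readings are deliberately left configurable rather than
resolved:

- **Dose transform.** As printed, the model is linear in dose
  (`dose_transform: identity`). Evaluated at the published cohort's median
  doses, however, the printed formula yields predicted risks near 0.95,
  irreconcilable with the published mean predicted risk of 36.2%; the
  model's ancestors use square-root dose transforms. Both `identity`
  (default, the formula as printed) and `sqrt` are implemented; the
  transform in force is stated in the report and run log, and the pipeline
  never switches silently. The transform is a single switch applied to both
  aggregated dose features.
- **SMG combination.** The formula writes one mean-dose term for two
  glands. `smg_combination` selects volume-weighted `combined` (default),
  equal-weight `mean`, or `sum`. When only summary mean doses are stored
  (no DVHs or volumes), `combined` falls back to equal weights — identical
  to `mean` for two glands — under an explicit fallback flag, enabled by
  default in the pipeline.

## Dosimetry

Cumulative DVHs (dose bins in Gy; fraction of structure volume receiving at
least each dose) are differentiated with midpoint bin representatives —
unbiased for piecewise-uniform curves — and reduced to volume-weighted mean
doses. EQD2 conversion uses the linear-quadratic map
`EQD2 = D (d + α/β) / (2 + α/β)` with α/β = 3 Gy and per-bin fraction dose
`d = D / n_fractions` (uniform fractionation of each dose level across the
course, the convention matching simultaneous-integrated-boost delivery).
The map is the identity at 2 Gy per fraction and strictly increasing, so
DVH validity is preserved. When a record stores only per-gland mean doses,
EQD2 is applied to the mean itself; this is exact for a uniform gland dose
and a documented approximation otherwise (the run log says so).

## Cohort assembly

Records pass a sequential inclusion cascade — treatment year 2012–2024,
allowed tumor site, curative prescribed dose ≥ 50 Gy, glands contoured, at
least one follow-up inside the analysis window, then the exclusion flags
plan adaptation → brachytherapy boost → reirradiation. Each removed record
is attributed to its *first* failing criterion, so the tally is a flow
chart without double counting and re-application removes nothing. Records
with no in-window follow-up are tallied under a dedicated
`no_followup_in_window` criterion.

The endpoint is grade ≥ 2 xerostomia at the follow-up nearest 6 months
within the window (default 5–24 months; a 5–12-month window reproduces the
sensitivity analysis and is flagged as such in the report). Ties are broken
toward the earlier visit, which is closer to the 6-month standard in
expectation. A missing baseline category scores zero; the raw category is
retained on the record so baseline-aware analyses stay possible.

Cohort comparisons use Pearson chi-square tests (no continuity correction)
on categorical count tables — categories with zero expected counts are
dropped with a warning — and Welch two-sample t-tests from summary
mean/SD/n for continuous variables, with significance at p < 0.05.

## Validation metrics

- **Calibration-in-the-large**: mean predicted risk vs observed rate, plus
  the offset-form intercept (MLE of `logit π = a + lp` with `lp` fixed).
- **Calibration intercept and slope**: joint MLE of `logit π = a + b·lp`.
  The intercept is reported from this joint fit (the weak-calibration
  convention); the offset-form intercept is reported separately, since
  published reports do not always state which convention they use.
- **Calibration curve**: equal-count bins of sorted predictions (remainder
  spread over the lowest bins; tied boundaries merged with a warning);
  abscissae are per-bin mean predicted probabilities, stated in the report.
- **Hosmer–Lemeshow**: `Σ (O_g − n_g p̄_g)² / (n_g p̄_g (1 − p̄_g))` over the
  same bins. Degrees of freedom default to g − 2 (the development-data
  convention); `df = g` is available and is the statistically calibrated
  choice for fully external validation, where no parameter was estimated
  from the data — simulations under a correctly specified model show
  rejection at the nominal 5% with df = g and ~11% with df = g − 2.
- **AUC**: rank-sum estimator with midrank ties (scikit-learn); **Brier**:
  mean squared error; **log-likelihood**: Bernoulli sum.

All logistic fits use iteratively reweighted least squares (statsmodels
GLM, binomial family), 100 iterations maximum, relative tolerance 1e-10;
non-finite or runaway coefficients (|coef| > 50) raise a fitting error with
a separation diagnostic, as do constant outcomes.

## Model updating and the closed test

Three nested updates are folded back into absolute coefficients so the
updated object is a complete, self-contained model:

- *intercept*: `logit π = a + lp` (offset form); new intercept `β₀ + a`.
- *recalibration*: `logit π = a + b·lp`; new intercept `a + b·β₀`, dose
  coefficients `b·βᵢ`, and baseline scores `b·score` — scaling the scores
  keeps the folded model exactly equivalent to `a + b·lp`. On an all-zero-
  baseline cohort this is indistinguishable from leaving the scores alone.
- *revision*: free intercept and both dose coefficients on the transformed
  features. When baseline scores vary in the cohort, the original score
  enters as one additional free coefficient (so the recalibrated model
  stays nested inside the revision — with the scores as a fixed offset the
  log-likelihood ordering can invert); with `refit_baseline`, per-category
  effects are estimated instead. In an all-zero-baseline cohort the term
  drops out.

The closed testing procedure fits the hierarchy M0 (original, 0 free
parameters) ⊂ M1 (1) ⊂ M2 (2) ⊂ M3 (3, plus baseline parameters when
applicable), asserts the log-likelihood ordering on every run, and tests M3
against each simpler candidate with likelihood-ratio chi-square tests at
α = 0.05, accepting the simplest candidate not rejected:
M3 vs M0 → M3 vs M1 → M3 vs M2. This controls the overall probability of
an unnecessary update at α.

## Decision curves

Treating patients with predicted risk ≥ t (closed at the threshold, stated
in the report) gives net benefit `TP/n − (FP/n) · t/(1−t)`, compared with
treat-all and treat-none policies over a default grid 0.05–0.60 in steps of
0.05, always including the clinically anchored 0.30.

## Synthetic study conditions

The generator emulates the validation registry's published marginal
structure; it is the test bed for every stage and defines the default
study conditions:

- per-gland physical mean doses from log-normal marginals anchored at the
  published medians (28.3, 16.2, 65.2, 46.2 Gy), with sigma fit by least
  squares to the published quartiles (median exact by construction; the
  residual quantifies log-asymmetry), joined by a Gaussian copula with
  exchangeable correlation ρ = 0.4 — a sensitivity knob, not an estimate,
  since no joint dose information is published — and clipped to 0.5–80 Gy;
- tumor-site, treatment-year and prescription-band frequencies from the
  published cohort table; follow-up times on 5–24 months from a scaled
  Beta(2, 4.64) whose median matches the published 10.3 months (only the
  median and range are published; the Beta shape is a documented choice);
- baseline xerostomia recorded for 15% of patients, distributed
  83/16/1% none/mild/moderate-severe among those;
- outcomes drawn from `logit π = δa + δb · lp_true` with neutral defaults
  (0, 1). The default true model is a *synthetic construct*: the published
  dose coefficients under the square-root transform with intercept −1.59,
  calibrated once so the default cohort's event prevalence is the
  registry's ~30% (the printed identity-transform formula cannot produce
  that prevalence at the published dose levels). Every visit of a patient
  carries a grade consistent with the drawn outcome, so endpoint
  derivation is unambiguous;
- a pre-filter pool: 61/34/71 disjoint records flagged for plan
  adaptation, brachytherapy boost and reirradiation are appended so the
  inclusion cascade reproduces the published 840 → 674 flow exactly.

`slope_miscalibration_scenario` fixes the conditions for power analyses:
the published identity-transform model as truth, δb = 1.36 (the published
recalibrated-to-original coefficient scale), δa = −4.50 recentring the
event rate to ~30%, and baseline recording off (the validation analysis
assumed a zero baseline score for everyone). Under these conditions the
closed test selects recalibration in ~86% of replicates at n = 674, while
under the null (data from the model itself) it keeps the original model in
~97%.

What passing tests on synthetic cohorts do **not** show: the generator has
no spatial dose structure, no site-specific dose correlations, no
follow-up attrition or recovery dynamics, and its outcome mechanism is the
assumed logistic form itself — so the tests certify the correctness of the
procedures, not the clinical transportability of any model.

## Problem sizes and numerics

Default analyses run at the registry's n = 674. Monte-Carlo suites use 500
replicates for closed-test operating characteristics, 1000 for
Hosmer–Lemeshow type-I error, and n = 10⁵ for large-sample parameter
recovery (calibration slope 1.00 ± 0.05). Probabilities are clipped at
1e-12 before logit transforms; DVH volume tolerance is 1e-9; the
mean-dose construction in `generate_dvh` is exact to 1e-6 by rescaling.
Reports store full precision; rounding happens only at presentation.

## Known limitations

- The identity/sqrt ambiguity of the published formula cannot be resolved
  from the publication alone; both are first-class options and the report
  states which was used.
- EQD2 of a stored mean dose is an approximation to the mean of an
  EQD2-converted DVH (exact only for uniform dose).
- The Hosmer–Lemeshow default df = g − 2 is conservative territory for
  external validation; use `df = g` there.
- No shrinkage or penalized updating, no confidence intervals on net
  benefit, no time-to-event modeling of xerostomia recovery.
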