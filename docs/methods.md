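# Methods

This note documents the statistical content of `macerisk`: the models it
fits, the calibration of its synthetic cohort generator, the numerical
choices, and the limits of what its tests demonstrate.

## Setting

Subjects are HCC patients starting an anti-angiogenic drug. Each carries
baseline cardiovascular covariates, a follow-up time in days, and an
event code: 0 censored, 1 MACE (heart failure, acute coronary syndrome,
cerebrovascular accident, or peripheral ischemia), 2 non-cardiovascular
death. Because mortality is high (median survival under a year),
non-CV death is treated as a competing event in every analysis, never as
censoring — except where a score's published definition requires it
(Harrell's cause-specific C).

## Risk scores

**ESC-2022 cardio-oncology tier.** The guideline's baseline-risk
proforma is a checklist of items graded M1 (1 point), M2 (2 points), H,
VH. The tier algorithm: any VH item ⇒ very-high; else any H item or a
moderate-point sum ≥ 5 ⇒ high; else sum 2–4 ⇒ moderate; else low. The
algorithm is code; the item→grade mapping is *data*, shipped as YAML and
editable, because the guideline's per-drug proformas differ and the
grades actually applied in a given registry must be reconstructable. The
default catalogue grades the arterial items (ischemic cardiac disease,
peripheral arterial disease, prior stroke, heart failure history) VH,
hypertension H, prior venous thromboembolism M2, age 80+ M2, and the
remaining factors (diabetes, dyslipidemia, CKD, smoking, obesity, age
65–79, prior cardiotoxic treatment) M1. This grading is the unique one
consistent with the per-class covariate distributions of the calibration
registry (e.g. diabetics appear in the low class, so diabetes cannot
carry 2 points; no hypertensive appears below the high class, so
hypertension must be an H trigger). Biomarker and imaging items (BNP,
troponin, LVEF) are omitted: they are measured only when clinically
indicated and cannot be derived from a boolean covariate table.

**CARDIOSOR.** Additive points: hypertension, diabetes, dyslipidemia 1
each; age ≥ 65 (inclusive) 2; prior stroke / ischemic cardiac disease /
peripheral vascular disease 3. The 3-point vascular item is awarded once
if any of the three is present — the published score lists them as a
single item and this keeps the range at [0, 8], so the ≤ 4 / > 4
dichotomy stays meaningful; a switch enables per-condition accumulation
for sensitivity checks. Missing covariates are rejected by default
(explicit 0/1 required); an opt-in mode imputes absent-with-warning.

## Competing-risks estimation

**Aalen–Johansen.** `F_k(t) = Σ_{t_j ≤ t} S(t_j−) d_kj / n_j` with
`S` the all-cause Kaplan–Meier left limit. The pointwise variance is the
Aalen-type delta-method estimator; Greenwood-style terms are zeroed when
a risk set is exhausted (`n_j = d_j`). With no events of the requested
cause the CIF is identically zero (not an error). The "1-year risk" is
the CIF at 365.25 days; the "cumulative risk" horizon defaults to the
last observed event time, and both are reported per class.

**Fine–Gray regression.** The subdistribution partial likelihood keeps a
subject with a competing event in the cause-1 risk set after their death
with weight `w_i(t) = G(t−)/G(T_i−)`, `G` the Kaplan–Meier of the
censoring distribution (both event types censor the censoring process;
at tied times events remain in the censoring risk set — the convention
of the reference implementations, against which the fitter agrees to
1e-9 on fixtures with and without ties). Ties among cause-1 events use
the Breslow approximation by default (Efron optional). Weights are
floored at 1e-10.

Newton–Raphson maximizes the weighted partial likelihood, with risk-set
sums organised as prefix/suffix cumulative sums (O(n log n) per
iteration). Convergence: max |gradient| < 1e-8, or Newton decrement
g'I⁻¹g < 1e-10 — the decrement criterion matters at n ≳ 10⁴, where
summation noise floors the gradient above the absolute tolerance while
the coefficients are already determined to ~1e-5 in curvature norm
(standard errors are ≥ 1e-2 throughout). Step halving guards against
overshoot; a coefficient passing |β| > 15 raises a separation error
naming the covariate; non-convergence raises an error carrying the
iteration trace.

Variance is the sandwich estimator built from per-subject score
residuals. It ignores the (second-order) contribution of estimating `G`;
on registry-shaped data the resulting 95% CIs cover the truth at
94–96% (checked by simulation), and the coefficients themselves match
the reference implementation exactly. CIs are normal-theory on the log
scale: `exp(β ± 1.96·se)`. Information criteria: `AIC = −2ℓ + 2k`,
`BIC = −2ℓ + k log m` with `m` the number of cause-1 events (the
standard sample size for partial-likelihood criteria; total n is
available as an option). Significance threshold 0.05, two-sided Wald.

**Univariable screen.** One Fine–Gray fit per binary risk factor, no
multiplicity adjustment (matching how such tables are reported); factors
with zero positives are flagged inestimable rather than raising.

## Concordance

A pair (i, j) is comparable iff i had a cause-1 event and `T_i < T_j`
(or `T_i = T_j` with j a non-event); pairs tied in both time and status
are excluded; score ties credit 1/2. *Harrell (cause-specific)*:
competing deaths censored at their event time. *Wolbers*: competing
deaths recoded as censored at τ = the longest observed follow-up, so a
subject dying MACE-free stays comparable — as a non-event — with every
earlier MACE. Class-valued scores are mapped to integer ranks
(low = 0 … very-high = 3) before concordance; both C variants are
invariant to strictly monotone transforms, so the rank choice is
immaterial.

CIs come from the jackknife variance of Somers' D (`D = 2C − 1`),
computed in O(n²) via per-subject pair aggregates. The paired score
comparison uses the jackknife covariance of the two D statistics
(delta-method z-test, two-sided), with a seeded bootstrap (B = 1000)
fallback if the jackknife variance degenerates. The comparison is
defined for the Harrell variant only — the Wolbers construction does not
come with a comparison test — mirroring how such results are reported.
Degenerate (constant) scores return C = 0.5 with a warning. Simulated
type-I error of the comparison at α = 0.05 is ≤ 0.07.

## Synthetic cohort generator

The generator's defaults *are* the study conditions of the calibration
registry (n = 843; class proportions 259/78/389/89 of the 815 subjects
with complete competing-risk data; class sHRs 1.575 / 2.513 / 8.836
versus low; low-class cumulative MACE incidence 1.7%; competing death
median 10.2 months; horizon 1123 days — the longest observed time to
MACE). Two presets coexist: the sHR-primary default (class sHRs exact,
class CIFs implied: very-high 14.1%) used for parameter recovery, and a
CIF-primary preset (class CIFs set to the registry's cumulative-risk
column exactly, sHRs implied) used for calibration checks
(`config_from_class_cifs`).

**Outcome model** — indirect Fine–Gray scheme. With linear predictor η,
the lifetime cause-1 probability is `P1 = 1 − (1 − p)^exp(η)` with p the
reference-class CIF at the horizon τ. Cause-1 times follow
`F1(t; η) = 1 − (1 − p·q(t))^exp(η)` with the truncated-exponential time
warp `q(t) = (1 − e^{−t/θ})/(1 − e^{−τ/θ})`, drawn by inverse transform
conditional on cause 1. θ = 160 days puts the median latent time to MACE
at ~111 days, matching the registry. This scheme makes the true
subdistribution hazard ratio exactly `exp(η)` at every t — the property
the recovery tests rely on. Subjects not assigned cause 1 draw an
exponential non-CV death time (median 10.2 months; a per-class hazard
multiplier is available for stress tests). The calibration is infeasible
only if some class's implied `P1` reaches 1, which raises a
configuration error naming the class.

**Censoring** is administrative: uniform over the potential-follow-up
window implied by the registry's enrollment span (45–153 months), which
begins beyond the event horizon. Consequences: the full-horizon CIF is
exactly estimable, and essentially every latent MACE is observed —
consistent with the registry, whose raw MACE count (34/843 = 4.0%)
nearly equals its model-implied marginal incidence (~4.3%), implying
censoring there almost never preceded MACE. An early-dropout exponential
component is available (off by default). One tension is documented
rather than resolved: the registry reports both a 10.2-month median
survival and an 11.3-month median follow-up, and no independent-censoring
model can reproduce both simultaneously (the median of min(T, C) cannot
exceed the median of T); the generator prioritizes the mortality and
event-count calibration, and its realized median follow-up is ~10
months.

**Profiles.** Covariates are independent Bernoulli draws within class at
the registry's per-class prevalences; ages are uniform integers within
the class-specific interquartile range. Two classes are not fully
explained by the tabulated covariates, so the generator carries residual
items: prior stroke at 11.8% in the very-high class, and a synthetic
"other high-risk finding" item in the high class. The latter is the one
exception to within-class independence: it targets non-hypertensive
class members (at the conditional rate preserving its 19.5% marginal),
because real high-tier membership *requires* an H trigger. With these,
scoring generated profiles with the default catalogue reproduces the
configured class proportions to ~1 pp.

**Modes.** `class_conditional`: a latent class drives the hazard
directly (all calibration and recovery analyses). `profile`: covariates
→ scores → hazards, driven by the scored ESC class, the CARDIOSOR point
count (per-point log-sHR), or the CARDIOSOR class (end-to-end pipeline
checks and the sensitivity rerun, where viral-etiology subjects receive
the sensitivity-preset class sHRs). Identical config + seed yields an
identical cohort (single PCG64 stream).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: covariate correlations within class beyond
the residual-item rule (only marginals are published), class-dependent
competing mortality, informative censoring, measurement error in the
score inputs, and any deviation of real MACE hazards from the
proportional-subdistribution form. Parameter recovery on these cohorts
demonstrates the estimators, not the clinical validity of the scores.

## Problem sizes

Recovery studies use the median fitted sHR over 50 replicate cohorts of
n = 20,000 (40,000 for the etiology subgroup, so the viral stratum keeps
~28,000 subjects); calibration checks use cohorts of n = 50,000
(replicate-averaged where a single cohort's Monte-Carlo noise would
dominate the reported estimate) and 4,000 replicates of the registry's
own n = 843 for the marginal incidence; the discrimination comparison
uses 200 replicates of n = 2,000 (≈ 80 events each, enough for stable
C estimates). These sizes keep every study's Monte-Carlo error well
inside the tolerances it is checked against.

## Known limitations

* The sandwich variance omits the censoring-KM estimation term; CIs are
  mildly conservative/anticonservative depending on censoring intensity
  (94–96% observed coverage under the shipped designs).
* The jackknife CI for C and the comparison test assume asymptotic
  normality of Somers' D; with very few events (< ~15) they are rough.
* Sparse strata (e.g. a class with < 5 events) yield unstable sHRs; a
  class with zero events is dropped from the regression with a warning
  and flagged inestimable rather than fitted.
* The ESC catalogue reconstructs a plausible grading consistent with the
  calibration registry; registries applying different gradings must ship
  their own catalogue (that is why it is data, not code).
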