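# macerisk

Cardiovascular risk stratification for hepatocellular-carcinoma (HCC)
patients on anti-angiogenic therapy, analysed under competing risks.

Anti-VEGF drugs (sorafenib and related tyrosine-kinase inhibitors) carry a
real risk of major adverse cardiovascular events — heart failure, acute
coronary syndrome, stroke, peripheral ischemia (MACE). Because HCC itself
is rapidly lethal, naive time-to-MACE analyses are distorted: most
patients die of their cancer before a cardiovascular event can occur.
`macerisk` implements the full validation pipeline for two bedside risk
scores in this setting, treating non-cardiovascular death as a competing
event throughout. It is aimed at biostatisticians and clinical
methodologists validating baseline cardiovascular risk scores on
time-to-event registry data.

## What it computes

**Risk scores** (`macerisk.scoring`)

* *ESC-2022 cardio-oncology tier*: catalogued risk items graded M1 (1 pt),
  M2 (2 pts), H or VH. Any VH item ⇒ very-high tier; any H item or a
  moderate-point sum ≥ 5 ⇒ high; point sum 2–4 ⇒ moderate; else low. The
  item→grade mapping is guideline data and ships as an editable YAML
  catalogue (`macerisk/data/esc_items.yaml`).
* *CARDIOSOR*: 1 pt each for hypertension, diabetes, dyslipidemia; 2 pts
  for age ≥ 65; 3 pts for prior stroke / ischemic cardiac disease /
  peripheral vascular disease; points ≤ 4 ⇒ low risk, > 4 ⇒ high.

**Competing-risks estimation** (`macerisk.competing`)

* Aalen–Johansen cumulative incidence
  `F_k(t) = Σ_{t_j ≤ t} S(t_j−) d_kj / n_j` with an Aalen-type variance.
* Fine–Gray subdistribution-hazard regression: competing-event subjects
  stay in the cause-1 risk set with inverse-probability-of-censoring
  weights `G(t)/G(T_i)`; Newton–Raphson maximization of the weighted
  partial likelihood, robust (sandwich) variance, subdistribution hazard
  ratios (sHR) with normal-theory 95% CIs, and information criteria
  `AIC = −2ℓ + 2k`, `BIC = −2ℓ + k·log(events)`.

**Discrimination** (`macerisk.concordance`)

* Harrell's C with competing deaths censored at their event time, and the
  Wolbers adaptation (competing deaths recoded as censored at the longest
  follow-up), both with jackknife CIs on Somers' D, plus a paired
  comparison test between two scores.

**Synthetic cohorts** (`macerisk.simulate`)

A generator calibrated to a published multicenter Italian registry of 843
sorafenib-treated HCC patients: ESC class proportions, class sHRs, a 1.7%
low-class cumulative MACE incidence, competing mortality with a
10.2-month median, per-class covariate prevalences, and an 1123-day event
horizon. Outcomes follow the indirect Fine–Gray scheme, so the true sHRs
equal the configured coefficients exactly — which is what makes every
downstream stage testable without any registry data.

**Pipeline** (`macerisk.pipeline`) — `run_validation` ties it together:
scoring → per-class cumulative incidences (1-year and full horizon) →
four Fine–Gray model forms (ESC 4-class, CARDIOSOR 2-class, ESC
dichotomized, CARDIOSOR linear) → AIC/BIC → concordance with comparisons
against the ESC 4-class reference; `subgroup_run` reruns everything on a
profile-filtered subset (e.g. viral etiology).

## Worked example

```python
from macerisk import default_config, simulate_outcomes, run_validation

cohort = simulate_outcomes(default_config(n=3000, seed=17, mode="profile"))
report = run_validation(cohort.profiles, cohort.records, seed=17)
print(report.to_text())
```

prints (abridged):

```
ESC_4CLASS
  CLASS              N (%)    EVENTS (%)   1-YR %   CUM %     sHR            95% CI        P
  low           975 (32.5)     20 (16.5)      1.8     2.1 1 (ref)
  moderate      323 (10.8)       4 (3.3)      1.2     1.2   0.602       0.205-1.768    0.356
  high         1410 (47.0)     53 (43.8)      3.5     3.8   1.845       1.103-3.087   0.0197
  very_high      292 (9.7)     44 (36.4)     13.0    15.1   7.816      4.607-13.262 2.48e-14
  AIC 1862.6  BIC 1871.0
...
CONCORDANCE
  esc_4class             Harrell 0.670 (0.618-0.722)  P -      Wolbers 0.681 (0.632-0.729)
  cardiosor_2class       Harrell 0.627 (0.583-0.671)  P 0.017  Wolbers 0.633 (0.590-0.676)
  cardiosor_linear       Harrell 0.671 (0.619-0.724)  P 0.918  Wolbers 0.677 (0.626-0.727)
```

Reading it: in this simulated cohort the very-high ESC tier carries an
estimated sHR of 7.8 (truth 8.836; 44 events) versus the low tier, a
cumulative MACE incidence of 15.1% at the horizon versus 2.1%, and the
four-class ESC score discriminates better than the dichotomized CARDIOSOR
(Wolbers C 0.681 vs 0.633, paired Harrell comparison p = 0.017) while the
linear CARDIOSOR score is competitive (p = 0.918) — the qualitative
pattern the registry analysis reports. The moderate tier, with 4 events,
illustrates the instability of sparse strata.

The same machinery runs from the shell:

```sh
macerisk simulate --seed 13 --out-prefix cohort_
macerisk score --cohort cohort_profiles.csv --out scores.csv
macerisk validate --profiles cohort_profiles.csv --records cohort_records.csv --out report/
macerisk validate --profiles cohort_profiles.csv --records cohort_records.csv --subgroup viral --out report_viral/
```

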