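# Default ESC-2022 cardio-oncology baseline risk-item catalogue for
# VEGF-pathway inhibitors, as applied to a sorafenib-treated HCC cohort.
#
# Severity codes: M1 (moderate, 1 point), M2 (moderate, 2 points),
# H (high-risk trigger), VH (very-high-risk trigger). H/VH items carry no
# numeric points; they act directly on the tier.
#
# Grades are guideline data, not algorithm: edit this file (or ship your
# own) to change the grading without touching code. Biomarker/imaging
# items (BNP, troponin, LVEF) are deliberately omitted: they are assessed
# only when clinically indicated and cannot be graded from a boolean
# covariate table.
items:
  heart_failure_history:
    label: Heart failure or cardiomyopathy
    severity: VH
    field: heart_failure_history
  ischemic_heart_disease:
    label: Ischemic cardiac disease (MI, angina, PCI, CABG)
    severity: VH
    field: ischemic_heart_disease
  peripheral_arterial_disease:
    label: Peripheral arterial occlusive disease
    severity: VH
    field: peripheral_arterial_disease
  prior_stroke:
    label: Prior cerebrovascular accident or TIA
    severity: VH
    field: prior_stroke
  hypertension:
    label: Arterial hypertension
    severity: H
    field: hypertension
  venous_thromboembolism_history:
    label: Prior venous thromboembolism (DVT or PE)
    severity: M2
    field: venous_thromboembolism_history
  diabetes:
    label: Diabetes mellitus
    severity: M1
    field: diabetes
  dyslipidemia:
    label: Dyslipidemia / hyperlipidemia
    severity: M1
    field: dyslipidemia
  chronic_kidney_disease:
    label: Chronic kidney disease
    severity: M1
    field: chronic_kidney_disease
  smoker:
    label: Current or recent smoking habit
    severity: M1
    field: smoker
  obesity:
    label: Obesity (BMI >= 30)
    severity: M1
    field: obesity
  prior_cancer_treatment_cardiotoxic:
    label: Previous cardiotoxic cancer treatment
    severity: M1
    field: prior_cancer_treatment_cardiotoxic
  age_65_79:
    label: Age 65-79 years
    severity: M1
    field: age
    age_min: 65
    age_max: 79
  age_80_plus:
    label: Age 80 years or older
    severity: M2
    field: age
    age_min: 80
  other_esc_high_item:
    label: Other high-risk finding on baseline cardiovascular work-up
      (synthetic residual item used by the cohort generator to account for
      high-tier membership not explained by the tabulated covariates)
    severity: H
    field: extra
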