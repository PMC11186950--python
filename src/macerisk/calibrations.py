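"""Calibration presets for the synthetic cohort generator.

All defaults emulate a multicenter Italian registry of 843 HCC patients
treated with sorafenib (2010-2018): ESC-2022 class proportions
259/78/389/89 (of the 815 with complete competing-risk data), class
subdistribution hazard ratios vs the low class, a 1.7% full-horizon
cumulative MACE incidence in the low class, competing (non-CV) death
with a 10.2-month median, and an event horizon of 1123 days (the
longest observed time to MACE). Per-class covariate prevalences and age
interquartile ranges reproduce the registry's baseline table.
"""

from __future__ import annotations

DAYS_PER_MONTH = 30.4375

#: Full-horizon calibration horizon (days): longest observed time to MACE.
DEFAULT_HORIZON_DAYS = 1123.0

#: Time scale (days) of the conditional MACE-time distribution; chosen so
#: the median latent time to MACE is ~111 days, the registry's median.
DEFAULT_MACE_TIME_SCALE_DAYS = 111.0 / 0.6931471805599453

#: ESC four-class preset: proportions and sHRs vs low; baseline CIF is the
#: low-class full-horizon cumulative incidence.
ESC_4CLASS = {
    "class_proportions": {
        "low": 259 / 815,
        "moderate": 78 / 815,
        "high": 389 / 815,
        "very_high": 89 / 815,
    },
    "shr": {"low": 1.0, "moderate": 1.575, "high": 2.513, "very_high": 8.836},
    "baseline_cif": 0.017,
    "reference": "low",
}

#: ESC four-class full-horizon cumulative incidences (CIF-primary preset,
#: for calibration checks keyed on the cumulative-risk column).
ESC_4CLASS_CIFS = {"low": 0.017, "moderate": 0.027, "high": 0.043, "very_high": 0.150}

#: CARDIOSOR dichotomized (<=4 vs >4 points) preset.
CARDIOSOR_2CLASS = {
    "class_proportions": {"low": 784 / 815, "high": 31 / 815},
    "shr": {"low": 1.0, "high": 4.666},
    "baseline_cif": 0.038,
    "reference": "low",
}

#: ESC dichotomized (very-high vs all other classes) preset.
ESC_DICHOTOMIZED = {
    "class_proportions": {"other": 726 / 815, "very_high": 89 / 815},
    "shr": {"other": 1.0, "very_high": 5.336},
    "baseline_cif": 0.030,
    "reference": "other",
}

#: CARDIOSOR as a linear predictor: sHR per point.
CARDIOSOR_LINEAR = {"shr_per_point": 1.431, "baseline_cif": 0.017}

#: Viral-etiology sensitivity preset. Only the very-high-vs-low sHR,
#: the linear CARDIOSOR sHR and the dichotomized CARDIOSOR sHR were
#: reported for the subgroup; moderate/high fall back to the full-cohort
#: values.
SENSITIVITY_VIRAL = {
    "shr": {"low": 1.0, "moderate": 1.575, "high": 2.513, "very_high": 7.346},
    "shr_per_point": 1.542,
    "shr_cardiosor_dichotomized": 4.061,
    "baseline_cif": 0.017,
    "viral_fraction": 0.709,
}

#: Competing-death and follow-up calibration.
COMPETING_DEATH_MEDIAN_MONTHS = 10.2
MEDIAN_FOLLOWUP_MONTHS = 11.3
#: Administrative censoring window (months): potential follow-up implied by
#: the registry's enrollment span (Jan 2010 - Dec 2018, closure Sep 2022).
ADMIN_CENSORING_WINDOW_MONTHS = (45.0, 153.0)

#: Per-class covariate prevalences (fractions) from the registry's
#: baseline table (classes low / moderate / high / very_high).
#: prior_stroke in the very-high class and the "other high-risk finding"
#: extra item in the high class are synthetic residual items calibrated so
#: that scoring the generated profiles with the default catalogue
#: round-trips the configured class proportions; the baseline table leaves
#: those class memberships unexplained by its listed covariates.
COVARIATE_PREVALENCES = {
    "sex_male": {"low": 0.860, "moderate": 0.805, "high": 0.806, "very_high": 0.905},
    "viral_etiology": {"low": 0.724, "moderate": 0.597, "high": 0.688, "very_high": 0.568},
    "hypertension": {"low": 0.0, "moderate": 0.0, "high": 0.805, "very_high": 0.632},
    "diabetes": {"low": 0.079, "moderate": 0.646, "high": 0.348, "very_high": 0.442},
    "dyslipidemia": {"low": 0.008, "moderate": 0.122, "high": 0.070, "very_high": 0.200},
    "ischemic_heart_disease": {"low": 0.0, "moderate": 0.0, "high": 0.0, "very_high": 0.853},
    "chronic_kidney_disease": {"low": 0.004, "moderate": 0.061, "high": 0.043, "very_high": 0.095},
    "obesity": {"low": 0.030, "moderate": 0.195, "high": 0.090, "very_high": 0.126},
    "smoker": {"low": 0.072, "moderate": 0.427, "high": 0.170, "very_high": 0.116},
    "peripheral_arterial_disease": {"low": 0.0, "moderate": 0.0, "high": 0.0, "very_high": 0.200},
    "prior_stroke": {"low": 0.0, "moderate": 0.0, "high": 0.0, "very_high": 0.118},
    "other_esc_high_item": {"low": 0.0, "moderate": 0.0, "high": 0.195, "very_high": 0.0},
}

#: Per-class age interquartile ranges (years); ages drawn uniformly within.
AGE_IQR = {
    "low": (53, 67),
    "moderate": (66, 71),
    "high": (65, 78),
    "very_high": (68, 78),
}
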