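"""Rule-based cardiovascular risk scores.

Two scores are computed from a baseline profile:

* **ESC-2022 cardio-oncology tier** — catalogue items graded M1 (1 pt),
  M2 (2 pts), H or VH. Any VH item puts the subject in the very-high
  tier; any H item, or a moderate-point sum >= 5, in the high tier;
  a moderate-point sum of 2-4 in the moderate tier; otherwise low.
* **CARDIOSOR** — an additive point score built for sorafenib-treated
  HCC patients: 1 point each for hypertension, diabetes and
  dyslipidemia; 2 points for age >= 65; 3 points (awarded once) for a
  history of stroke, ischemic cardiac disease or peripheral vascular
  disease. Points <= 4 define the low-risk class, > 4 high risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalogue import MODERATE_POINTS, EscItemCatalogue
from .profiles import SubjectProfile

__all__ = [
    "EscAssessment",
    "CardiosorResult",
    "grade_esc_items",
    "esc_tier",
    "cardiosor_score",
    "score_cohort",
    "TIER_ORDER",
]

TIER_ORDER = ("low", "moderate", "high", "very_high")


class ScoringConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EscAssessment:
    graded: tuple  # of (item_code, severity)
    moderate_point_sum: int
    tier: str


@dataclass(frozen=True)
class CardiosorResult:
    points: int
    risk_class: str  # "low" iff points <= 4


def grade_esc_items(
    profile: SubjectProfile, catalogue: EscItemCatalogue
) -> list[tuple[str, str]]:
    """Return the catalogue items that apply to ``profile``.

    Each positive item is returned as ``(item_code, severity)``, in
    catalogue order. Unknown ``extra_items`` keys are a configuration
    error: they indicate a profile scored against the wrong catalogue.
    """
    if len(catalogue) == 0:
        raise ScoringConfigError("catalogue is empty")
    unknown = set(profile.extra_items) - {it.code for it in catalogue}
    if unknown:
        raise ScoringConfigError(
            f"subject {profile.subject_id!r}: extra_items keys not in catalogue: "
            f"{sorted(unknown)}"
        )
    return [(it.code, it.severity) for it in catalogue if it.applies(profile)]


def esc_tier(graded: list[tuple[str, str]]) -> EscAssessment:
    """Collapse graded items into the four-level ESC risk tier.

    Tier rules: very_high if any VH item; else high if any H item or the
    M1/M2 point sum is >= 5; else moderate if the point sum is 2-4; else
    low. Total on valid input; item order is irrelevant.
    """
    severities = [s for _, s in graded]
    bad = set(severities) - {"M1", "M2", "H", "VH"}
    if bad:
        raise ValueError(f"unknown severities: {sorted(bad)}")
    pts = sum(MODERATE_POINTS.get(s, 0) for s in severities)
    if "VH" in severities:
        tier = "very_high"
    elif "H" in severities or pts >= 5:
        tier = "high"
    elif pts >= 2:
        tier = "moderate"
    else:
        tier = "low"
    return EscAssessment(graded=tuple(graded), moderate_point_sum=pts, tier=tier)


def assess_esc(profile: SubjectProfile, catalogue: EscItemCatalogue) -> EscAssessment:
    """Grade and tier in one step."""
    return esc_tier(grade_esc_items(profile, catalogue))


def cardiosor_score(
    profile: SubjectProfile, accumulate_vascular: bool = False
) -> CardiosorResult:
    """CARDIOSOR points and dichotomous class.

    The 3-point vascular item (stroke / ischemic cardiac disease /
    peripheral vascular disease) is awarded once if any of the three is
    present, keeping the score in [0, 8]; ``accumulate_vascular=True``
    switches to per-condition accumulation for sensitivity checks.
    """
    vascular = (
        profile.prior_stroke,
        profile.ischemic_heart_disease,
        profile.peripheral_arterial_disease,
    )
    points = (
        int(profile.hypertension)
        + int(profile.diabetes)
        + int(profile.dyslipidemia)
        + 2 * int(profile.age >= 65)
    )
    if accumulate_vascular:
        points += 3 * sum(map(int, vascular))
    else:
        points += 3 * int(any(vascular))
    return CardiosorResult(points=points, risk_class="low" if points <= 4 else "high")


def score_cohort(
    profiles: list[SubjectProfile], catalogue: EscItemCatalogue
) -> pd.DataFrame:
    """Score every subject; one row per subject.

    Returns columns subject_id, esc_tier, esc_moderate_points,
    cardiosor_points, cardiosor_class.
    """
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate subject_id values: {sorted(set(dupes))[:5]}")
    rows = []
    for p in profiles:
        esc = assess_esc(p, catalogue)
        cs = cardiosor_score(p)
        rows.append(
            {
                "subject_id": p.subject_id,
                "esc_tier": esc.tier,
                "esc_moderate_points": esc.moderate_point_sum,
                "cardiosor_points": cs.points,
                "cardiosor_class": cs.risk_class,
            }
        )
    return pd.DataFrame(rows)
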