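"""Subject-level baseline profiles.

A :class:`SubjectProfile` carries the baseline cardiovascular covariates
recorded before the start of anti-angiogenic therapy. Both rule-based risk
scores (the ESC-2022 cardio-oncology tier and CARDIOSOR) and the synthetic
cohort generator operate on these profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["SubjectProfile", "read_profiles_csv", "write_profiles_csv", "BOOLEAN_FIELDS"]


class ProfileError(ValueError):
    """Raised when a profile (or cohort table) violates its invariants."""


#: Boolean covariates of a profile, in canonical column order.
BOOLEAN_FIELDS = (
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "smoker",
    "obesity",
    "chronic_kidney_disease",
    "ischemic_heart_disease",
    "peripheral_arterial_disease",
    "prior_stroke",
    "heart_failure_history",
    "venous_thromboembolism_history",
    "prior_cancer_treatment_cardiotoxic",
)


@dataclass(frozen=True)
class SubjectProfile:
    """Baseline covariates of one subject.

    ``obesity`` encodes BMI >= 30. ``extra_items`` holds additional
    catalogued ESC risk items (item code -> bool) that have no dedicated
    field; every key must exist in the active item catalogue.
    """

    subject_id: str
    age: int
    sex: str = "male"
    etiology: str = "viral"
    hypertension: bool = False
    diabetes: bool = False
    dyslipidemia: bool = False
    smoker: bool = False
    obesity: bool = False
    chronic_kidney_disease: bool = False
    ischemic_heart_disease: bool = False
    peripheral_arterial_disease: bool = False
    prior_stroke: bool = False
    heart_failure_history: bool = False
    venous_thromboembolism_history: bool = False
    prior_cancer_treatment_cardiotoxic: bool = False
    extra_items: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (18 <= int(self.age) <= 120):
            raise ProfileError(
                f"subject {self.subject_id!r}: age {self.age} outside [18, 120]"
            )
        if self.sex not in ("male", "female"):
            raise ProfileError(f"subject {self.subject_id!r}: sex must be male/female")
        if self.etiology not in ("viral", "nonviral"):
            raise ProfileError(
                f"subject {self.subject_id!r}: etiology must be viral/nonviral"
            )


def _coerce_bool(value, column: str, subject: str, assume_absent: bool) -> bool:
    if pd.isna(value):
        if assume_absent:
            return False
        raise ProfileError(
            f"subject {subject!r}: missing value in column {column!r} "
            "(explicit 0/1 required; use assume_absent=True to impute false)"
        )
    if value in (0, 1, True, False, "0", "1"):
        return bool(int(value))
    raise ProfileError(f"subject {subject!r}: column {column!r} must be 0/1, got {value!r}")


def read_profiles_csv(path, assume_absent: bool = False) -> list[SubjectProfile]:
    """Read a cohort CSV into profiles.

    The CSV has one header row; columns are named exactly like the
    :class:`SubjectProfile` fields, booleans encoded 0/1, age in integer
    years. Unrecognised columns are folded into ``extra_items``.
    Missing booleans are rejected unless ``assume_absent`` imputes false.
    """
    df = pd.read_csv(path)
    return profiles_from_frame(df, assume_absent=assume_absent)


def profiles_from_frame(df: pd.DataFrame, assume_absent: bool = False) -> list[SubjectProfile]:
    if "subject_id" not in df.columns or "age" not in df.columns:
        raise ProfileError("cohort table requires subject_id and age columns")
    known = {f.name for f in fields(SubjectProfile)} - {"extra_items"}
    extra_cols = [c for c in df.columns if c not in known]
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ProfileError(f"duplicate subject_id values: {dupes[:5]}")
    out = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        sid = str(rec["subject_id"])
        kwargs = {"subject_id": sid, "age": int(rec["age"])}
        if "sex" in rec:
            kwargs["sex"] = str(rec["sex"])
        if "etiology" in rec:
            kwargs["etiology"] = str(rec["etiology"])
        for col in BOOLEAN_FIELDS:
            if col in rec:
                kwargs[col] = _coerce_bool(rec[col], col, sid, assume_absent)
        extra = {
            c: _coerce_bool(rec[c], c, sid, assume_absent) for c in extra_cols
        }
        kwargs["extra_items"] = extra
        out.append(SubjectProfile(**kwargs))
    return out


def profiles_to_frame(profiles: Iterable[SubjectProfile]) -> pd.DataFrame:
    rows = []
    extra_keys: list[str] = []
    profiles = list(profiles)
    for p in profiles:
        for k in p.extra_items:
            if k not in extra_keys:
                extra_keys.append(k)
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "age": p.age,
            "sex": p.sex,
            "etiology": p.etiology,
        }
        for col in BOOLEAN_FIELDS:
            row[col] = int(getattr(p, col))
        for k in extra_keys:
            row[k] = int(bool(p.extra_items.get(k, False)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_csv(profiles: Iterable[SubjectProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)
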