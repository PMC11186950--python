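"""Scoring module: ESC tier rules, CARDIOSOR points, cohort scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from macerisk.catalogue import EscItemCatalogue, CatalogueItem
from macerisk.profiles import ProfileError, profiles_from_frame
from macerisk.scoring import (
    ScoringConfigError,
    TIER_ORDER,
    cardiosor_score,
    esc_tier,
    grade_esc_items,
    score_cohort,
)

from conftest import make_profile


class TestGradeItems:
    def test_no_positive_items_gives_empty_list(self, catalogue):
        assert grade_esc_items(make_profile(), catalogue) == []

    def test_ischemic_heart_disease_is_very_high(self, catalogue):
        graded = grade_esc_items(
            make_profile(ischemic_heart_disease=True), catalogue
        )
        assert graded == [("ischemic_heart_disease", "VH")]

    def test_diabetes_and_smoking_graded_per_catalogue(self, catalogue):
        graded = grade_esc_items(
            make_profile(diabetes=True, smoker=True), catalogue
        )
        assert set(graded) == {("diabetes", "M1"), ("smoker", "M1")}

    def test_age_bands(self, catalogue):
        assert ("age_65_79", "M1") in grade_esc_items(make_profile(age=65), catalogue)
        assert ("age_80_plus", "M2") in grade_esc_items(make_profile(age=83), catalogue)
        assert grade_esc_items(make_profile(age=64), catalogue) == []

    def test_unknown_extra_item_names_the_key(self, catalogue):
        p = make_profile(extra_items={"not_a_real_item": True})
        with pytest.raises(ScoringConfigError, match="not_a_real_item"):
            grade_esc_items(p, catalogue)

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ScoringConfigError):
            grade_esc_items(make_profile(), EscItemCatalogue([]))


class TestEscTier:
    @pytest.mark.parametrize(
        "graded, points, tier",
        [
            ([], 0, "low"),
            ([("x", "VH"), ("y", "H"), ("z", "M2")], 2, "very_high"),
            ([("a", "M1"), ("b", "M2"), ("c", "M2")], 5, "high"),
            ([("a", "M2"), ("b", "M1")], 3, "moderate"),
            ([("a", "H")], 0, "high"),
            ([("a", "M2")], 2, "moderate"),
            ([("a", "M1")], 1, "low"),
        ],
    )
    def test_tier_rules(self, graded, points, tier):
        res = esc_tier(graded)
        assert res.moderate_point_sum == points
        assert res.tier == tier

    def test_unknown_severity_rejected(self):
        with pytest.raises(ValueError):
            esc_tier([("a", "X1")])

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.sampled_from(["M1", "M2", "H", "VH"])),
            max_size=8,
        ),
        st.sampled_from(["M1", "M2", "H", "VH"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_adding_an_item_never_lowers_the_tier(self, graded, extra_sev):
        graded = [(f"i{i}", s) for i, s in graded]
        before = TIER_ORDER.index(esc_tier(graded).tier)
        after = TIER_ORDER.index(esc_tier(graded + [("extra", extra_sev)]).tier)
        assert after >= before

    @given(st.permutations(
        [("a", "M1"), ("b", "M2"), ("c", "H"), ("d", "VH"), ("e", "M2")]
    ))
    @settings(max_examples=30, deadline=None)
    def test_tier_invariant_to_item_order(self, perm):
        assert esc_tier(list(perm)).tier == "very_high"


class TestCardiosor:
    @pytest.mark.parametrize(
        "kwargs, points, cls",
        [
            (dict(age=50), 0, "low"),
            (dict(age=70, hypertension=True, diabetes=True), 4, "low"),
            (dict(age=70, hypertension=True, diabetes=True, prior_stroke=True), 7, "high"),
            (dict(age=64, hypertension=True, diabetes=True, dyslipidemia=True), 3, "low"),
            (dict(age=65, hypertension=True, diabetes=True, dyslipidemia=True,
                  ischemic_heart_disease=True), 8, "high"),
        ],
    )
    def test_point_scheme(self, kwargs, points, cls):
        res = cardiosor_score(make_profile(**kwargs))
        assert (res.points, res.risk_class) == (points, cls)

    def test_vascular_item_awarded_once_by_default(self):
        p = make_profile(prior_stroke=True, ischemic_heart_disease=True,
                         peripheral_arterial_disease=True)
        assert cardiosor_score(p).points == 3
        assert cardiosor_score(p, accumulate_vascular=True).points == 9

    def test_range_is_exactly_0_to_8_by_enumeration(self):
        """Brute force over all 2^6 factor combinations x age in {64, 65}."""
        factors = ["hypertension", "diabetes", "dyslipidemia", "prior_stroke",
                   "ischemic_heart_disease", "peripheral_arterial_disease"]
        seen = set()
        for combo in itertools.product([False, True], repeat=6):
            for age in (64, 65):
                p = make_profile(age=age, **dict(zip(factors, combo)))
                res = cardiosor_score(p)
                expected = (
                    combo[0] + combo[1] + combo[2]
                    + 2 * (age >= 65) + 3 * any(combo[3:])
                )
                assert res.points == expected
                assert res.risk_class == ("low" if res.points <= 4 else "high")
                seen.add(res.points)
        assert seen == set(range(9))


class TestScoreCohort:
    def test_one_row_per_subject_and_frequencies(self, catalogue):
        profiles = [
            make_profile(subject_id="a", age=70, hypertension=True),
            make_profile(subject_id="b", age=50),
            make_profile(subject_id="c", age=80, ischemic_heart_disease=True),
        ]
        tab = score_cohort(profiles, catalogue)
        assert list(tab["subject_id"]) == ["a", "b", "c"]
        assert list(tab["esc_tier"]) == ["high", "low", "very_high"]
        assert list(tab["cardiosor_points"]) == [3, 0, 5]

    def test_duplicate_subject_id_rejected(self, catalogue):
        profiles = [make_profile(subject_id="a"), make_profile(subject_id="a")]
        with pytest.raises(ValueError, match="duplicate"):
            score_cohort(profiles, catalogue)


class TestProfileIO:
    def test_missing_boolean_rejected_unless_assume_absent(self):
        df = pd.DataFrame({"subject_id": ["a"], "age": [60],
                           "hypertension": [np.nan]})
        with pytest.raises(ProfileError, match="hypertension"):
            profiles_from_frame(df)
        (p,) = profiles_from_frame(df, assume_absent=True)
        assert p.hypertension is False

    def test_age_bounds_enforced(self):
        with pytest.raises(ProfileError):
            make_profile(age=17)
        with pytest.raises(ProfileError):
            make_profile(age=121)

    def test_unrecognized_columns_become_extra_items(self):
        df = pd.DataFrame({"subject_id": ["a"], "age": [60],
                           "other_esc_high_item": [1]})
        (p,) = profiles_from_frame(df)
        assert p.extra_items == {"other_esc_high_item": True}
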