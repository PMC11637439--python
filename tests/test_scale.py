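import itertools

import pytest
from hypothesis import given, settings, strategies as stst

from xpakit import scale
from xpakit.cohort import ClinicalEvent, Patient
from xpakit.features import MAJOR_SCORES, MINOR_FEATURES
from xpakit.scale import (
    FeatureProfile,
    classify,
    classify_cohort,
    profile_at_age,
    score_profile,
    score_trajectory,
)

# Independent copy of the scoring table used as a lookup oracle; kept
# literal on purpose so it cannot share a bug with the implementation.
ORACLE_MAJORS = {
    "delayed_milestones": -0.5,
    "hearing_decline_no_aid": -0.5,
    "mild_dev_delay": -1.0,
    "hyporeflexia_only": -1.0,
    "hearing_mild": -1.0,
    "hearing_moderate": -1.5,
    "gait_disturbance": -2.0,
    "moderate_dev_delay": -2.0,
    "hearing_severe": -2.5,
    "cannot_walk": -3.0,
    "severe_dev_delay": -3.0,
    "g_tube": -3.0,
    "hearing_profound": -3.0,
    "neuro_death": -4.0,
}


def oracle_total(majors, minors):
    worst = min((ORACLE_MAJORS[f] for f in majors), default=0.0)
    return worst - 0.1 * len(minors)


def profile(majors=(), minors=(), age=10.0):
    return FeatureProfile(
        age=age, active_major=frozenset(majors), active_minor=frozenset(minors)
    )


class TestScoreProfile:
    def test_empty_profile_scores_zero(self):
        assert score_profile(profile()).total == 0.0

    def test_worst_major_plus_additive_minors(self):
        sc = score_profile(
            profile(
                ("gait_disturbance", "cannot_walk", "g_tube"),
                ("peripheral_neuropathy", "dysphagia"),
            )
        )
        assert sc.total == pytest.approx(-3.2)

    def test_matches_exhaustive_lookup_oracle(self):
        # all subsets of a 7-feature major panel, with 0-3 minors
        panel = [
            "delayed_milestones", "mild_dev_delay", "hearing_moderate",
            "gait_disturbance", "hearing_severe", "cannot_walk",
            "neuro_death",
        ]
        minors = list(MINOR_FEATURES)
        for r in range(len(panel) + 1):
            for majors in itertools.combinations(panel, r):
                for k in range(len(minors) + 1):
                    got = score_profile(
                        profile(majors, minors[:k])
                    ).total
                    assert got == pytest.approx(
                        oracle_total(majors, minors[:k])
                    ), (majors, k)

    def test_total_stays_in_score_range(self):
        sc = score_profile(profile(MAJOR_SCORES, MINOR_FEATURES))
        assert -4.3 <= sc.total <= 0

    @given(
        majors=stst.sets(stst.sampled_from(sorted(MAJOR_SCORES))),
        minors=stst.sets(stst.sampled_from(sorted(MINOR_FEATURES))),
        extra=stst.sampled_from(sorted(MAJOR_SCORES) + sorted(MINOR_FEATURES)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_adding_a_feature_never_raises_the_total(
        self, majors, minors, extra
    ):
        base = score_profile(profile(majors, minors)).total
        if extra in MINOR_FEATURES:
            grown = score_profile(profile(majors, minors | {extra})).total
        else:
            grown = score_profile(profile(majors | {extra}, minors)).total
        assert grown <= base + 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        "total,expected",
        [
            (0.0, "mild"),
            (-0.5, "mild"),
            (-0.74, "mild"),
            (-0.75, "intermediate"),
            (-1.0, "intermediate"),
            (-1.1, "intermediate"),
            (-1.99, "intermediate"),
            (-2.0, "severe"),
            (-4.3, "severe"),
        ],
    )
    def test_band_boundaries(self, total, expected):
        assert classify(total) == expected


class TestProfilesAndTrajectories:
    def test_age10_profile_of_severe_index_patient(self, cohort):
        p = cohort.patient("XP363BE")
        prof = profile_at_age(p, 10)
        assert prof.active_major == {"delayed_milestones", "gait_disturbance"}
        assert not prof.active_minor
        assert score_profile(prof).total == -2.0

    def test_profile_at_age_zero_is_empty(self, cohort):
        prof = profile_at_age(cohort.patient("XP12BE"), 0)
        assert not prof.active_major and not prof.active_minor

    def test_hearing_feature_active_at_onset_age(self, cohort):
        prof = profile_at_age(cohort.patient("XP12BE"), 17)
        assert "hearing_mild" in prof.active_major

    def test_only_worst_hearing_band_retained(self, cohort):
        prof = profile_at_age(cohort.patient("XP363BE"), 21)
        assert "hearing_profound" in prof.active_major
        assert "hearing_severe" not in prof.active_major

    def test_trajectory_monotone_for_every_fixture_patient(self, cohort):
        ages = [0, 1, 2, 5, 8, 10, 12, 15, 17, 20, 22, 30, 40, 45]
        for p in cohort.patients:
            traj = score_trajectory(p, ages)
            totals = [t for _, t in traj]
            assert all(b <= a + 1e-12 for a, b in zip(totals, totals[1:])), (
                p.patient_id
            )

    def test_severe_patient_trajectory_endpoints(self, cohort):
        p = cohort.patient("XP363BE")
        traj = dict(score_trajectory(p, [10, 16, 22]))
        assert traj[10] == -2.0
        assert -4.0 < traj[16] <= -3.0   # cannot walk + G-tube + dysphagia
        assert traj[22] == pytest.approx(-4.1)  # neurologic death + minor

    def test_no_events_means_flat_zero(self):
        p = Patient(patient_id="P", sex="M", last_followup_age=20.0)
        assert score_trajectory(p, [0, 10, 20]) == [(0, 0.0), (10, 0.0),
                                                    (20, 0.0)]

    def test_nonneurologic_death_does_not_score(self):
        p = Patient(
            patient_id="P", sex="M", last_followup_age=20.0,
            death_age=20.0, death_neurologic=False,
            events=(ClinicalEvent("seizures", 5.0),),
        )
        assert scale.score_at_age(p, 20).total == pytest.approx(-0.1)


class TestClassifyCohort:
    def test_index_patients_classified_as_reported(self, cohort):
        classes = classify_cohort(cohort, 10)
        assert classes["XP363BE"] == "severe"
        assert classes["XP12BE"] == "intermediate"
        assert classes["XP53BE"] == "mild"

    def test_patients_not_followed_to_evaluation_age_are_flagged(self, cohort):
        classes = classify_cohort(cohort, 50)
        assert classes["XP607BE"] == "unclassifiable"  # last follow-up 45

    def test_evaluation_age_zero_makes_event_free_patients_mild(self, cohort):
        classes = classify_cohort(cohort, 0, require_followup=False)
        assert classes["XP53BE"] == "mild"
        assert classes["XP363BE"] == "mild"
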