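"""Neurological severity scoring and age-10 classification.

The total score of a feature profile is::

    total = min(score of active major features, default 0)
            - 0.1 * (number of active minor features)

Major features are *not* additive — the worst (most negative) active
major feature sets the major component — while each active minor feature
subtracts 0.1. Totals therefore live in [-4.3, 0].

Classification at an evaluation age (10 years by default) uses three
bands anchored on the named scores 0 / -1 / <= -2:

* severe: total <= -2
* intermediate: -2 < total <= MILD_THRESHOLD
* mild: total > MILD_THRESHOLD (default -0.75, so an isolated -0.5
  early-childhood delay stays mild and -1 with minors stays intermediate)
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import CohortTable, Patient
from .features import (
    HEARING_FEATURES,
    MAJOR_SCORES,
    MINOR_FEATURES,
    MINOR_SCORE,
)

#: boundary between mild and intermediate bands (mild: total > threshold)
MILD_THRESHOLD = -0.75
#: boundary between intermediate and severe bands (severe: total <= -2)
SEVERE_THRESHOLD = -2.0

MILD, INTERMEDIATE, SEVERE = "mild", "intermediate", "severe"
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class FeatureProfile:
    """Features active in a patient at a given age."""

    age: float
    active_major: frozenset[str]
    active_minor: frozenset[str]


@dataclass(frozen=True)
class SeverityScore:
    major_component: float
    minor_count: int

    @property
    def total(self) -> float:
        return round(self.major_component + MINOR_SCORE * self.minor_count, 10)


def profile_at_age(patient: Patient, age: float) -> FeatureProfile:
    """Features with onset at or before ``age`` (cumulative convention).

    Among mutually exclusive hearing bands only the worst (most negative)
    is retained; death from neurological degeneration contributes the
    ``neuro_death`` feature once ``death_age <= age``.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    majors: set[str] = set()
    minors: set[str] = set()
    for ev in patient.events:
        if ev.onset_age <= age:
            if ev.feature in MINOR_FEATURES:
                minors.add(ev.feature)
            else:
                majors.add(ev.feature)
    if (
        patient.death_neurologic
        and patient.death_age is not None
        and patient.death_age <= age
    ):
        majors.add("neuro_death")
    hearing = [f for f in HEARING_FEATURES if f in majors]
    if len(hearing) > 1:
        worst = min(hearing, key=lambda f: MAJOR_SCORES[f])
        majors -= set(hearing) - {worst}
    return FeatureProfile(
        age=age, active_major=frozenset(majors), active_minor=frozenset(minors)
    )


def score_profile(profile: FeatureProfile) -> SeverityScore:
    """Apply the scale: worst major feature plus additive minors."""
    major = min(
        (MAJOR_SCORES[f] for f in profile.active_major), default=0.0
    )
    return SeverityScore(
        major_component=major, minor_count=len(profile.active_minor)
    )


def classify(score: SeverityScore | float) -> str:
    """Map a total score to the mild / intermediate / severe bands."""
    total = score.total if isinstance(score, SeverityScore) else float(score)
    if total <= SEVERE_THRESHOLD:
        return SEVERE
    if total <= MILD_THRESHOLD:
        return INTERMEDIATE
    return MILD


def score_at_age(patient: Patient, age: float) -> SeverityScore:
    return score_profile(profile_at_age(patient, age))


def classify_cohort(
    cohort: CohortTable,
    evaluation_age: float = 10.0,
    require_followup: bool = True,
) -> dict[str, str]:
    """Classify every patient at ``evaluation_age``.

    Patients not observed to the evaluation age (last follow-up and death
    both earlier) are reported ``unclassifiable`` when
    ``require_followup`` is set.
    """
    out: dict[str, str] = {}
    for p in cohort.patients:
        observed_to = max(p.last_followup_age, p.death_age or 0.0)
        if require_followup and observed_to < evaluation_age:
            out[p.patient_id] = UNCLASSIFIABLE
            continue
        out[p.patient_id] = classify(score_at_age(p, evaluation_age))
    return out


def score_trajectory(
    patient: Patient, ages
) -> list[tuple[float, float]]:
    """Total score along an ascending age grid.

    Cumulative-feature semantics make the trajectory non-increasing; a
    neurological death pins later points at -4 minus active minors.
    """
    ages = list(ages)
    if any(b < a for a, b in zip(ages, ages[1:])):
        raise ValueError("ages must be sorted ascending")
    return [(a, score_at_age(patient, a).total) for a in ages]


def feature_contributions(profile: FeatureProfile) -> dict[str, float]:
    """Per-feature contributions for audit reports (majors show their
    table score; minors -0.1 each)."""
    out = {f: MAJOR_SCORES[f] for f in sorted(profile.active_major)}
    out.update({f: MINOR_SCORE for f in sorted(profile.active_minor)})
    return out
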