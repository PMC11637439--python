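"""Synthetic-data generators emulating the statistical structure of an
XP-A natural-history cohort, post-UV survival assays, and splice-donor
geometry — so every pipeline stage is testable offline.

All generators are pure functions of (config, seed).

Cohort onsets and death ages are log-normal, parameterised by their
median (positive support, median = exp(mu)); the default medians are
the published per-group onset medians (developmental delay 1/5/18
years, gait disturbance 5.5/28/37.5, peripheral neuropathy 7/21/39,
hearing loss 11/19/-, dysphagia 16/24/39; death 22/44.5/-) with a
common log-scale sd of 0.25, giving the clean between-group separation
at age 10 that the cohort exhibits. Group sizes default to 8/5/5
(severe/intermediate/mild).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import DoseResponse
from .cohort import ClinicalEvent, CohortTable, Patient
from .seqtools import (
    BASES,
    EXONIC_PART,
    WINDOW,
    DonorMatrix,
    score_donor,
)

# ---------------------------------------------------------------------------
# cohort simulation

#: per-group onset-age medians (years) per feature; None = feature absent
DEFAULT_ONSET_MEDIANS: dict[str, dict[str, float | None]] = {
    "severe": {
        "moderate_dev_delay": 1.0,
        "gait_disturbance": 5.5,
        "peripheral_neuropathy": 7.0,
        "hearing_mild": 11.0,
        "dysphagia": 16.0,
    },
    "intermediate": {
        "mild_dev_delay": 5.0,
        "gait_disturbance": 28.0,
        "peripheral_neuropathy": 21.0,
        "hearing_mild": 19.0,
        "dysphagia": 24.0,
    },
    "mild": {
        "mild_dev_delay": 18.0,
        "gait_disturbance": 37.5,
        "peripheral_neuropathy": 39.0,
        "hearing_mild": None,
        "dysphagia": 39.0,
    },
}

#: per-group median death age (years); None = deaths not expected
DEFAULT_DEATH_MEDIANS: dict[str, float | None] = {
    "severe": 22.0,
    "intermediate": 44.5,
    "mild": None,
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-condition parameters for the cohort generator."""

    n_severe: int = 8
    n_intermediate: int = 5
    n_mild: int = 5
    onset_medians: dict = field(
        default_factory=lambda: {
            g: dict(f) for g, f in DEFAULT_ONSET_MEDIANS.items()
        }
    )
    death_medians: dict = field(
        default_factory=lambda: dict(DEFAULT_DEATH_MEDIANS)
    )
    log_sd: float = 0.25        # log-scale sd of onset/death distributions
    censor_age: float = 45.0    # administrative right-censoring age

    def __post_init__(self) -> None:
        if min(self.n_severe, self.n_intermediate, self.n_mild) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.log_sd < 0 or self.censor_age <= 0:
            raise ValueError("log_sd must be >= 0 and censor_age positive")
        dd = [
            self.onset_medians[g].get("moderate_dev_delay")
            or self.onset_medians[g].get("mild_dev_delay")
            for g in ("severe", "intermediate", "mild")
        ]
        if all(x is not None for x in dd) and not (dd[0] < dd[1] < dd[2]):
            raise ValueError(
                "onset medians must be ordered severe < intermediate < mild"
            )


def _lognormal(rng: np.random.Generator, median: float, log_sd: float) -> float:
    if log_sd == 0:
        return float(median)
    return float(median * np.exp(rng.normal(0.0, log_sd)))


def simulate_cohort(
    cfg: CohortSimConfig = CohortSimConfig(), seed: int = 0
) -> tuple[CohortTable, dict[str, str]]:
    """Simulate a cohort; returns (cohort, ground-truth class per id)."""
    rng = np.random.default_rng(seed)
    patients: list[Patient] = []
    truth: dict[str, str] = {}
    sizes = {
        "severe": cfg.n_severe,
        "intermediate": cfg.n_intermediate,
        "mild": cfg.n_mild,
    }
    idx = 0
    for group, n in sizes.items():
        for _ in range(n):
            idx += 1
            pid = f"SIM{idx:03d}"
            death_median = cfg.death_medians.get(group)
            death_age = (
                _lognormal(rng, death_median, cfg.log_sd)
                if death_median is not None
                else None
            )
            if death_age is not None and death_age > cfg.censor_age:
                death_age = None  # administratively censored before death
            observed_to = (
                death_age if death_age is not None else cfg.censor_age
            )
            events = []
            for feature, median in cfg.onset_medians[group].items():
                if median is None:
                    continue
                onset = _lognormal(rng, median, cfg.log_sd)
                if onset <= observed_to:
                    events.append(
                        ClinicalEvent(
                            feature=feature,
                            onset_age=round(onset, 4),
                            source="simulated",
                        )
                    )
            patients.append(
                Patient(
                    patient_id=pid,
                    sex="F" if idx % 2 else "M",
                    events=tuple(sorted(events, key=lambda e: e.onset_age)),
                    death_age=round(death_age, 4)
                    if death_age is not None
                    else None,
                    death_neurologic=death_age is not None,
                    last_followup_age=round(observed_to, 4),
                    family_id=f"SIMFAM{idx:03d}",
                    reported_class=group,
                )
            )
            truth[pid] = group
    return CohortTable(patients=patients), truth


# ---------------------------------------------------------------------------
# post-UV survival assay simulation

def simulate_survival_assay(
    d37: float,
    doses=(2.0, 4.0, 8.0, 12.0, 16.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> DoseResponse:
    """Exponential post-UV survival with multiplicative log-normal noise:
    ``S(D) = exp(-D/d37) * exp(N(0, noise_sd))``."""
    if d37 <= 0:
        raise ValueError("d37 must be positive")
    rng = np.random.default_rng(seed)
    doses = tuple(float(d) for d in doses)
    responses = []
    for d in doses:
        s = np.exp(-d / d37)
        if noise_sd > 0:
            s *= np.exp(rng.normal(0.0, noise_sd))
        responses.append(float(s))
    return DoseResponse(doses=doses, responses=tuple(responses))


# ---------------------------------------------------------------------------
# donor-site geometry simulation

@dataclass(frozen=True)
class DonorScenario:
    """A planted new-donor geometry: a weak natural donor at
    ``boundary`` and a single-base substitution that creates a strong
    donor ``planted_offset`` bases downstream."""

    sequence: str
    substitution: tuple[int, str]
    boundary: int           # 0-based position of the natural boundary
    planted_offset: int
    threshold: float


def simulate_donor_sequence(
    matrix: DonorMatrix,
    planted_offset: int = 8,
    seed: int = 0,
    length: int = 80,
    threshold: float | None = None,
) -> DonorScenario:
    """Construct a sequence with a weak native donor site and a
    substitution creating an above-threshold donor at ``planted_offset``.

    The default threshold sits 2 bits under the matrix maximum, so only
    near-consensus windows qualify. The background is resampled until no
    reference window reaches the threshold (a validity requirement of the
    planted geometry, guaranteed by construction for any seed).
    """
    if planted_offset == 0:
        raise ValueError("planted_offset must be nonzero")
    if threshold is None:
        threshold = matrix.max_score - 2.0
    consensus = matrix.consensus
    rng = np.random.default_rng(seed)

    boundary = length // 3
    new_boundary = boundary + planted_offset
    new_start = new_boundary - EXONIC_PART
    if not (0 <= new_start and new_start + WINDOW <= length):
        raise ValueError("planted offset does not fit in the sequence")

    # weaken the natural site: consensus with two low-weight bases
    def worst_base(pos: int) -> str:
        row = matrix.weights[pos]
        return BASES[int(np.argmin(row))]

    weak = list(consensus)
    weak[4] = worst_base(4)
    weak[5] = worst_base(5)
    weak_site = "".join(weak)

    # planted site: consensus with one wrong base; the substitution
    # restores it
    sub_window_pos = 4  # +1 intronic position of the new donor window
    planted = list(consensus)
    planted[sub_window_pos] = worst_base(sub_window_pos)

    for _ in range(1000):
        seq = list(rng.choice(list(BASES), size=length))
        nat_start = boundary - EXONIC_PART
        seq[nat_start : nat_start + WINDOW] = weak_site
        seq[new_start : new_start + WINDOW] = planted
        ref = "".join(seq)
        top = max(
            score_donor(ref[s : s + WINDOW], matrix)
            for s in range(length - WINDOW + 1)
        )
        if top <= threshold:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not construct a background below threshold")

    substitution = (new_start + sub_window_pos, consensus[sub_window_pos])
    return DonorScenario(
        sequence=ref,
        substitution=substitution,
        boundary=boundary,
        planted_offset=planted_offset,
        threshold=float(threshold),
    )
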