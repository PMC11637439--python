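"""Neurological feature vocabulary and the severity scoring table.

The scale distinguishes *major* features, which set the backbone of the
score (the worst active major feature defines the major component), from
*minor* features, which are additive and each contribute -0.1. Scores run
from 0 (no symptoms) to -4 (death from neurological degeneration); with
all three minor features active the floor is -4.3.

Hearing-loss features are banded on the four-frequency pure-tone average
(4F-PTA, dB hearing loss); only the worst active band counts.
"""

from __future__ import annotations

# Major features -> score contribution (the minimum over active majors is
# the major component of the total).
MAJOR_SCORES: dict[str, float] = {
    "delayed_milestones": -0.5,      # delayed milestones / early-childhood neurocognitive delay
    "hearing_decline_no_aid": -0.5,  # hearing decline, no hearing aid required
    "mild_dev_delay": -1.0,          # IQ 50-85
    "hyporeflexia_only": -1.0,       # hyporeflexia/areflexia as the only finding
    "hearing_mild": -1.0,            # 4F-PTA 20-40 dBHL, aided
    "hearing_moderate": -1.5,        # 4F-PTA 40-70 dBHL, aided
    "gait_disturbance": -2.0,        # spasticity or ataxia affecting gait
    "moderate_dev_delay": -2.0,      # IQ 35-50
    "hearing_severe": -2.5,          # 4F-PTA 70-95 dBHL, aided
    "cannot_walk": -3.0,
    "severe_dev_delay": -3.0,        # IQ < 35
    "g_tube": -3.0,                  # gastrostomy-tube dependency
    "hearing_profound": -3.0,        # 4F-PTA > 95 dBHL, aided
    "neuro_death": -4.0,             # deceased from neurological degeneration
}

# Minor features are additive, -0.1 each.
MINOR_SCORE = -0.1
MINOR_FEATURES: frozenset[str] = frozenset(
    {"peripheral_neuropathy", "dysphagia", "seizures"}
)

FEATURES: frozenset[str] = frozenset(MAJOR_SCORES) | MINOR_FEATURES

# Mutually exclusive hearing bands, mildest to worst; an optional 4F-PTA
# value attached to an event must fall in the band (half-open, dBHL).
HEARING_FEATURES: tuple[str, ...] = (
    "hearing_decline_no_aid",
    "hearing_mild",
    "hearing_moderate",
    "hearing_severe",
    "hearing_profound",
)
HEARING_BANDS: dict[str, tuple[float, float]] = {
    "hearing_mild": (20.0, 40.0),
    "hearing_moderate": (40.0, 70.0),
    "hearing_severe": (70.0, 95.0),
    "hearing_profound": (95.0, float("inf")),
}

# Developmental-delay feature keyed on IQ, when an IQ measurement is
# available; the clinical token is used otherwise.
IQ_BANDS: tuple[tuple[float, float, str], ...] = (
    (50.0, 85.0, "mild_dev_delay"),
    (35.0, 50.0, "moderate_dev_delay"),
    (float("-inf"), 35.0, "severe_dev_delay"),
)


def dev_delay_feature_for_iq(iq: float) -> str | None:
    """Map a full-scale IQ to the corresponding developmental-delay feature.

    Returns ``None`` for IQ above 85 (no delay under the scale).
    """
    for lo, hi, feature in IQ_BANDS:
        if lo <= iq < hi:
            return feature
    return None


def feature_score(feature: str) -> float:
    """Score contribution of a single feature (majors from the table,
    minors -0.1)."""
    if feature in MAJOR_SCORES:
        return MAJOR_SCORES[feature]
    if feature in MINOR_FEATURES:
        return MINOR_SCORE
    raise KeyError(f"unknown feature: {feature!r}")
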