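"""DNA-repair assay metrics: D37 from post-UV survival curves, UDS
percent-of-normal, and host-cell-reactivation (HCR) relative luciferase
activity.

Post-UV survival is modelled single-hit exponential, ``S(D) =
exp(-D/D0)``; the D37 — the UVC dose leaving 37% (e^-1) of cells
surviving — equals D0. The default fit is least squares of ``ln S``
against dose through the origin; a free-intercept option accommodates
shouldered curves (then D37 is the dose where the fitted line reaches
``ln S = -1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DoseResponse:
    """UV dose series (J m^-2, ascending) with survival fractions."""

    doses: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses differ in length")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if any(b < a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be ascending")

    @classmethod
    def from_counts(cls, doses, counts) -> "DoseResponse":
        """Normalise raw counts by the dose-0 reference."""
        doses = tuple(float(d) for d in doses)
        counts = [float(c) for c in counts]
        if 0.0 not in doses:
            raise ValueError("raw counts require a dose-0 reference point")
        ref = counts[doses.index(0.0)]
        if ref <= 0:
            raise ValueError("dose-0 reference count must be positive")
        return cls(doses=doses, responses=tuple(c / ref for c in counts))


@dataclass(frozen=True)
class AssayResult:
    d37: float
    slope: float       # d ln(S) / d dose
    intercept: float   # ln S at dose 0 (0 when fixed)
    r_squared: float
    intercept_fixed: bool


def fit_d37(dr: DoseResponse, fix_intercept: bool = True) -> AssayResult:
    """Fit the exponential survival model and extract D37.

    Survival fractions above 1 are clipped to 1 with a warning
    (measurement noise); non-positive fractions are rejected because the
    log-linear fit is undefined there. At least 3 positive-dose points
    are required.
    """
    doses = np.asarray(dr.doses, dtype=float)
    resp = np.asarray(dr.responses, dtype=float)
    if np.any(resp <= 0):
        raise ValueError("survival fractions must be positive for the log fit")
    if np.any(resp > 1):
        warnings.warn(
            "survival fractions above 1 clipped to 1", stacklevel=2
        )
        resp = np.minimum(resp, 1.0)
    if len(doses) < 3:
        raise ValueError("need at least 3 dose-response points")
    log_s = np.log(resp)
    if fix_intercept:
        denom = float(np.sum(doses**2))
        if denom == 0:
            raise ValueError("all doses are zero")
        slope = float(np.sum(doses * log_s)) / denom
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(doses, log_s, 1)
        slope, intercept = float(slope), float(intercept)
    if slope >= 0:
        raise ValueError(
            "survival does not decline with dose; D37 undefined"
        )
    d37 = (-1.0 - intercept) / slope
    fitted = intercept + slope * doses
    ss_res = float(np.sum((log_s - fitted) ** 2))
    ss_tot = float(np.sum((log_s - log_s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AssayResult(
        d37=float(d37),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        intercept_fixed=fix_intercept,
    )


def uds_percent(patient_grains: float, normal_grains: float) -> float:
    """Unscheduled DNA synthesis as percent of the normal donor
    (grains per nucleus)."""
    if normal_grains <= 0:
        raise ValueError("normal grains-per-nucleus must be positive")
    if patient_grains < 0:
        raise ValueError("grains-per-nucleus cannot be negative")
    return 100.0 * patient_grains / normal_grains


def hcr_relative(luc_uv: float, luc_unirradiated: float) -> float:
    """Host-cell reactivation: UV-irradiated reporter activity as percent
    of the unirradiated control."""
    if luc_unirradiated <= 0:
        raise ValueError("unirradiated luciferase activity must be positive")
    if luc_uv < 0:
        raise ValueError("luciferase activity cannot be negative")
    return 100.0 * luc_uv / luc_unirradiated


def complementation_group(panel: dict[str, float]) -> str:
    """Identify the complementation group from a co-transfection panel:
    the cognate gene is the one whose co-transfection maximises relative
    HCR activity."""
    if not panel:
        raise ValueError("empty complementation panel")
    return max(panel, key=panel.__getitem__)
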