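"""Kaplan-Meier estimation and the k-group log-rank (Mantel-Cox) test,
implemented from first principles.

The product-limit estimator treats observations censored at an event
time as still at risk at that time (censoring tie-broken after events).
The log-rank statistic uses the hypergeometric variance with the
simultaneous-risk-set convention for ties and k-1 degrees of freedom;
p-values come from the chi-square upper tail with no continuity
correction.

Medians follow the convention that the median is the smallest event time
``t`` with ``S(t) <= 0.5``; when the curve hits 0.5 exactly at ``t`` and
a later event time exists, the median is the midpoint of the two
(switchable to the strict convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SurvivalObservation:
    """One subject: follow-up time, event indicator, optional group."""

    time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(f"time must be finite and positive: {self.time}")


@dataclass
class SurvivalCurve:
    """Product-limit step function with risk-set bookkeeping."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # n_i at each event time
    events: np.ndarray     # d_i at each event time
    censored: np.ndarray   # censorings in [t_i, t_{i+1})
    n: int                 # total observations

    def at(self, t: float) -> float:
        """S(t) for arbitrary t (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def km_estimate(obs) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``obs`` is an iterable of :class:`SurvivalObservation` (or
    ``(time, event)`` pairs). Raises on empty input.
    """
    obs = [
        o if isinstance(o, SurvivalObservation) else SurvivalObservation(*o)
        for o in obs
    ]
    if not obs:
        raise ValueError("km_estimate requires at least one observation")
    times = np.array([o.time for o in obs], dtype=float)
    events = np.array([o.event for o in obs], dtype=bool)

    event_times = np.unique(times[events])
    surv, n_risk, n_events, n_cens = [], [], [], []
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & events))
        s *= 1.0 - d_i / n_i
        upper = event_times[i + 1] if i + 1 < len(event_times) else np.inf
        c_i = int(np.sum((times >= t) & (times < upper) & ~events))
        surv.append(s)
        n_risk.append(n_i)
        n_events.append(d_i)
        n_cens.append(c_i)
    return SurvivalCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(n_risk, dtype=int),
        events=np.array(n_events, dtype=int),
        censored=np.array(n_cens, dtype=int),
        n=len(obs),
    )


NOT_REACHED = None


def km_median(curve: SurvivalCurve, averaging: bool = True):
    """Median survival time, or ``None`` when S never drops to 0.5.

    With ``averaging`` (the default), a curve sitting exactly at 0.5
    averages the crossing event time with the next event time.
    """
    below = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if len(below) == 0:
        return NOT_REACHED
    i = int(below[0])
    t = float(curve.times[i])
    if (
        averaging
        and abs(curve.survival[i] - 0.5) <= 1e-12
        and i + 1 < len(curve.times)
    ):
        return (t + float(curve.times[i + 1])) / 2.0
    return t


def logrank_test(groups: dict) -> LogRankResult:
    """k-group log-rank (Mantel-Cox) test.

    ``groups`` maps a label to its observations. Every group must be
    non-empty; k >= 2.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test requires at least two groups")
    parsed = {}
    for g in labels:
        obs = [
            o
            if isinstance(o, SurvivalObservation)
            else SurvivalObservation(*o)
            for o in groups[g]
        ]
        if not obs:
            raise ValueError(f"group {g!r} has zero observations")
        parsed[g] = (
            np.array([o.time for o in obs]),
            np.array([o.event for o in obs], dtype=bool),
        )

    k = len(labels)
    all_event_times = np.unique(
        np.concatenate([t[e] for t, e in parsed.values()])
    )
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in all_event_times:
        n_g = np.array(
            [np.sum(times >= t) for times, _ in parsed.values()], dtype=float
        )
        d_g = np.array(
            [
                np.sum((times == t) & events)
                for times, events in parsed.values()
            ],
            dtype=float,
        )
        n, d = n_g.sum(), d_g.sum()
        if n <= 0 or d == 0:
            continue
        observed += d_g
        expected += n_g * d / n
        if n > 1:
            # multivariate hypergeometric covariance of event counts
            frac = n_g / n
            factor = d * (n - d) / (n - 1)
            cov += factor * (np.diag(frac) - np.outer(frac, frac))

    z = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    chi2 = float(z @ np.linalg.pinv(v) @ z) if v.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LogRankResult(chi2=chi2, df=df, p=p)


@dataclass
class OnsetAnalysis:
    """Per-group onset curves with medians and the group comparison."""

    feature: str
    curves: dict = field(default_factory=dict)       # group -> SurvivalCurve
    medians: dict = field(default_factory=dict)      # group -> years or None
    n_per_group: dict = field(default_factory=dict)
    logrank: LogRankResult | None = None


def _observation_end(patient) -> float:
    return (
        patient.death_age
        if patient.death_age is not None
        else patient.last_followup_age
    )


def onset_analysis(
    cohort,
    feature: str,
    classes: dict[str, str],
    assessed: set[str] | None = None,
    averaging: bool = True,
) -> OnsetAnalysis:
    """Kaplan-Meier onset-age analysis of one feature across severity
    groups.

    Patients without the feature are right-censored at death or last
    follow-up; patients outside ``assessed`` (when given — e.g. features
    not evaluated in every patient) are excluded entirely.
    """
    by_group: dict[str, list[SurvivalObservation]] = {}
    for p in cohort.patients:
        g = classes.get(p.patient_id)
        if g is None or g == "unclassifiable":
            continue
        if assessed is not None and p.patient_id not in assessed:
            continue
        onset = next(
            (ev.onset_age for ev in p.events if ev.feature == feature), None
        )
        if onset is not None:
            ob = SurvivalObservation(time=max(onset, 1e-9), event=True,
                                     group=g)
        else:
            end = _observation_end(p)
            if end <= 0:
                continue
            ob = SurvivalObservation(time=end, event=False, group=g)
        by_group.setdefault(g, []).append(ob)

    result = OnsetAnalysis(feature=feature)
    for g, obs in by_group.items():
        curve = km_estimate(obs)
        result.curves[g] = curve
        result.medians[g] = km_median(curve, averaging=averaging)
        result.n_per_group[g] = len(obs)
    if len(by_group) >= 2:
        result.logrank = logrank_test(by_group)
    return result


def mortality_analysis(
    cohort,
    classes: dict[str, str],
    neurologic_only: bool = False,
    averaging: bool = True,
) -> OnsetAnalysis:
    """All-cause (default) or neurologic-death-only survival by severity
    group; living patients censored at last follow-up."""
    by_group: dict[str, list[SurvivalObservation]] = {}
    for p in cohort.patients:
        g = classes.get(p.patient_id)
        if g is None or g == "unclassifiable":
            continue
        if p.death_age is not None:
            is_event = p.death_neurologic or not neurologic_only
            ob = SurvivalObservation(time=p.death_age, event=is_event, group=g)
        else:
            if p.last_followup_age <= 0:
                continue
            ob = SurvivalObservation(
                time=p.last_followup_age, event=False, group=g
            )
        by_group.setdefault(g, []).append(ob)
    result = OnsetAnalysis(feature="survival")
    for g, obs in by_group.items():
        curve = km_estimate(obs)
        result.curves[g] = curve
        result.medians[g] = km_median(curve, averaging=averaging)
        result.n_per_group[g] = len(obs)
    if len(by_group) >= 2:
        result.logrank = logrank_test(by_group)
    return result
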