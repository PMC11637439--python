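"""Cohort domain types and tab-separated readers/writers.

A cohort is a set of patients, each carrying dated clinical events
(cumulative: once a feature's onset age has passed it stays active),
vital status, and zero to two germline allele identifiers that resolve
into a variant table. Files are long-format TSV, one event per row, with
``.`` for missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .features import FEATURES, HEARING_BANDS

#: sentinel allele identifier for a known-to-exist but unprinted allele
UNKNOWN_ALLELE = "unknown"

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "feature",
    "onset_age",
    "death_age",
    "last_followup_age",
    "allele1",
    "allele2",
]
OPTIONAL_COLUMNS = [
    "family_id",
    "death_neurologic",
    "hemizygous",
    "reported_class",
    "events_complete",
    "pta_db",
    "source",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file or object violates an invariant."""


@dataclass(frozen=True)
class ClinicalEvent:
    """A dated onset of one neurological feature."""

    feature: str
    onset_age: float
    pta_db: float | None = None  # 4F-PTA (dBHL) for hearing features
    source: str = ""             # provenance tag for fixture traceability

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise CohortValidationError(
                f"unknown feature {self.feature!r}; allowed: "
                + ", ".join(sorted(FEATURES))
            )
        if not (self.onset_age >= 0):
            raise CohortValidationError(
                f"onset_age must be >= 0, got {self.onset_age} "
                f"for {self.feature}"
            )
        if self.pta_db is not None:
            band = HEARING_BANDS.get(self.feature)
            if band is None:
                raise CohortValidationError(
                    f"{self.feature} does not take a 4F-PTA value"
                )
            lo, hi = band
            if not (lo <= self.pta_db < hi):
                raise CohortValidationError(
                    f"4F-PTA {self.pta_db} dBHL outside the "
                    f"{self.feature} band [{lo}, {hi})"
                )


@dataclass(frozen=True)
class Patient:
    """One cohort member: events, vital status, genotype."""

    patient_id: str
    sex: str  # 'M' or 'F'
    events: tuple[ClinicalEvent, ...] = ()
    death_age: float | None = None
    death_neurologic: bool = False
    last_followup_age: float = 0.0
    alleles: tuple[str, ...] = ()  # 0-2 variant identifiers
    hemizygous: bool = False
    family_id: str = ""
    reported_class: str | None = None  # clinically reported severity group
    events_complete: bool = True       # False: event detail only partly known
    notes: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise CohortValidationError(
                f"{self.patient_id}: sex must be M or F, got {self.sex!r}"
            )
        if len(self.alleles) > 2:
            raise CohortValidationError(
                f"{self.patient_id}: at most 2 alleles, got {self.alleles}"
            )
        if self.hemizygous and len(self.alleles) != 1:
            raise CohortValidationError(
                f"{self.patient_id}: hemizygous patients carry exactly one "
                f"allele identifier"
            )
        seen: dict[str, float] = {}
        for ev in self.events:
            if ev.feature in seen and seen[ev.feature] != ev.onset_age:
                raise CohortValidationError(
                    f"{self.patient_id}: conflicting onset ages for "
                    f"{ev.feature}: {seen[ev.feature]} vs {ev.onset_age}"
                )
            seen[ev.feature] = ev.onset_age
        if self.events:
            last_onset = max(ev.onset_age for ev in self.events)
            if self.last_followup_age < last_onset:
                raise CohortValidationError(
                    f"{self.patient_id}: last_followup_age "
                    f"{self.last_followup_age} precedes an event onset "
                    f"{last_onset}"
                )
            if self.death_age is not None and self.death_age < last_onset:
                raise CohortValidationError(
                    f"{self.patient_id}: death_age {self.death_age} "
                    f"precedes an event onset {last_onset}"
                )

    @property
    def genotyped(self) -> bool:
        return any(a != UNKNOWN_ALLELE for a in self.alleles)


@dataclass
class CohortTable:
    """Container tying patients to the variant identifiers they carry."""

    patients: list[Patient] = field(default_factory=list)
    variant_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dupes}")
        if self.variant_ids:
            for p in self.patients:
                for a in p.alleles:
                    if a != UNKNOWN_ALLELE and a not in self.variant_ids:
                        raise CohortValidationError(
                            f"{p.patient_id}: allele {a!r} does not resolve "
                            f"to a variant record"
                        )

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


def _parse_float(token) -> float | None:
    if token is None:
        return None
    s = str(token).strip()
    if s in (".", "", "nan", "NaN"):
        return None
    return float(s)


def _parse_bool(token, default: bool = False) -> bool:
    if token is None:
        return default
    s = str(token).strip()
    if s in (".", "", "nan", "NaN"):
        return default
    return s.lower() in ("1", "true", "yes")


def read_cohort(path) -> CohortTable:
    """Read a long-format cohort TSV (one event per row) into a
    :class:`CohortTable`.

    Rows sharing a ``patient_id`` are merged into one patient; a row whose
    ``feature`` is ``.`` contributes patient-level fields only. Conflicting
    duplicate events and unknown feature tokens raise
    :class:`CohortValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")

    patients: list[Patient] = []
    for pid, rows in df.groupby("patient_id", sort=False):
        first = rows.iloc[0]
        events = []
        for _, row in rows.iterrows():
            feat = row["feature"].strip()
            if feat in (".", ""):
                continue
            onset = _parse_float(row["onset_age"])
            if onset is None:
                raise CohortValidationError(
                    f"{pid}: event {feat} lacks an onset_age"
                )
            events.append(
                ClinicalEvent(
                    feature=feat,
                    onset_age=onset,
                    pta_db=_parse_float(row.get("pta_db")),
                    source=str(row.get("source", "") or ""),
                )
            )
        alleles = tuple(
            a for a in (first["allele1"].strip(), first["allele2"].strip())
            if a not in (".", "")
        )
        death_age = _parse_float(first["death_age"])
        patients.append(
            Patient(
                patient_id=str(pid),
                sex=first["sex"].strip(),
                events=tuple(events),
                death_age=death_age,
                death_neurologic=_parse_bool(first.get("death_neurologic")),
                last_followup_age=_parse_float(first["last_followup_age"])
                or 0.0,
                alleles=alleles,
                hemizygous=_parse_bool(first.get("hemizygous")),
                family_id=str(first.get("family_id", "") or ""),
                reported_class=(
                    str(first["reported_class"]).strip()
                    if "reported_class" in rows.columns
                    and first["reported_class"].strip() not in (".", "")
                    else None
                ),
                events_complete=_parse_bool(
                    first.get("events_complete"), default=True
                ),
            )
        )
    return CohortTable(patients=patients)


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return "."
        return f"{value:g}"
    return str(value) if str(value) else "."


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as long-format TSV; inverse of :func:`read_cohort`."""
    columns = COHORT_COLUMNS + OPTIONAL_COLUMNS
    rows = []
    for p in cohort.patients:
        base = {
            "patient_id": p.patient_id,
            "sex": p.sex,
            "death_age": _fmt(p.death_age),
            "last_followup_age": _fmt(p.last_followup_age),
            "allele1": _fmt(p.alleles[0] if len(p.alleles) > 0 else None),
            "allele2": _fmt(p.alleles[1] if len(p.alleles) > 1 else None),
            "family_id": _fmt(p.family_id),
            "death_neurologic": _fmt(p.death_neurologic),
            "hemizygous": _fmt(p.hemizygous),
            "reported_class": _fmt(p.reported_class),
            "events_complete": _fmt(p.events_complete),
        }
        if p.events:
            for ev in p.events:
                rows.append(
                    base
                    | {
                        "feature": ev.feature,
                        "onset_age": _fmt(ev.onset_age),
                        "pta_db": _fmt(ev.pta_db),
                        "source": _fmt(ev.source),
                    }
                )
        else:
            rows.append(
                base | {"feature": ".", "onset_age": ".", "pta_db": ".",
                        "source": "."}
            )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def with_variants(cohort: CohortTable, variant_ids) -> CohortTable:
    """Attach a variant-identifier universe, re-validating allele links."""
    return CohortTable(
        patients=list(cohort.patients), variant_ids=frozenset(variant_ids)
    )


__all__ = [
    "ClinicalEvent",
    "Patient",
    "CohortTable",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "with_variants",
    "UNKNOWN_ALLELE",
]
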