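"""Packaged encoding of the 18-patient NIH XP-A natural-history cohort.

Every encoded fact carries a ``source`` tag naming the published section
or figure it was read from. Facts reported only in figure cells that are
not legible in the published text are encoded as explicit unknowns
(``events_complete=False``, empty event lists, the ``unknown`` allele
sentinel), never guessed.

Conventions:

* ages in decimal years; "6 weeks" -> 0.12, "17 months" -> 1.42
  (two-decimal rounding);
* events never resolve — a feature stays active after its onset
  (progressive disease);
* sexes not individually printed are assigned to reproduce the published
  cohort totals (10 female, 8 male) and are tagged as such;
* XP120BE is encoded homozygous for p.Glu111* (only that variant is
  reported for the patient; zygosity inferred);
* XP591BE's unprinted second allele is the ``unknown`` sentinel.
"""

from __future__ import annotations

from .cohort import UNKNOWN_ALLELE, ClinicalEvent, CohortTable, Patient

_SEVERE_GAIT = (
    "all eight severe patients presented with gait disturbances due to "
    "spasticity or ataxia by age 10 years"
)
_SEX_AGG = "sex assigned to match printed cohort totals (10 F, 8 M)"
_C555_DD = (
    "c.555G>C patients had developmental delay (IQ of 50-85) by age 10 years"
)

# Identifiers for the 16 variants printed in the running text; the
# canonical id is the printed c. notation when available, else p.
V_288DEL = "c.288delT"
V_349DEL = "c.349_353delCTTAT"
V_315 = "c.315C>A"
V_324 = "c.324T>A"
V_338DEL = "c.338_339delTG"
V_603DEL = "c.603_607delAGAAG"
V_E111X = "p.Glu111*"
V_Q216X = "p.Gln216*"
V_555GC = "c.555G>C"
V_390AC = "c.390-1G>T"
V_C126W = "p.Cys126Trp"
V_R228X = "p.Arg228*"
V_IVS4 = "c.555+8A>G"
V_EX6DEL = "c.674_819del"
V_142DEL = "c.142delT"
V_R258FS = "p.Arg258Tyrfs*5"

FIXTURE_VARIANT_IDS = (
    V_288DEL, V_349DEL, V_315, V_324, V_338DEL, V_603DEL, V_E111X, V_Q216X,
    V_555GC, V_390AC, V_C126W, V_R228X, V_IVS4, V_EX6DEL, V_142DEL, V_R258FS,
)


def _ev(feature, age, source, pta=None):
    return ClinicalEvent(feature=feature, onset_age=age, pta_db=pta,
                         source=source)


def fixture_cohort() -> CohortTable:
    """The 18 NIH XP-A patients as printed in the study text."""
    sev = "severe"
    inter = "intermediate"
    mild = "mild"
    patients = [
        # ---- severe group (n = 8) -------------------------------------
        Patient(
            patient_id="XP363BE", sex="M", family_id="FAM-360",
            reported_class=sev, death_age=22.0, death_neurologic=True,
            last_followup_age=22.0,
            alleles=(V_288DEL, V_349DEL),
            events=(
                _ev("delayed_milestones", 1.42,
                    "delayed developmental milestones walking at 17 months"),
                _ev("gait_disturbance", 9.0,
                    "persistent toe walking that progressively became less "
                    "steady by age 9"),
                _ev("cannot_walk", 15.0,
                    "he then became non-ambulatory (after crawling to 15)"),
                _ev("g_tube", 15.0,
                    "required a G-tube due to dysphagia"),
                _ev("dysphagia", 15.0, "required a G-tube due to dysphagia"),
                _ev("hearing_severe", 17.0,
                    "at age 17 developed mild to severe bilateral hearing "
                    "loss"),
                _ev("hearing_profound", 20.0,
                    "by age 20 he was profoundly deaf"),
            ),
            notes="died at age 22 due to progressive neurological "
                  "complications",
        ),
        Patient(
            patient_id="XP360BE", sex="M", family_id="FAM-360",
            reported_class=sev, last_followup_age=10.0,
            alleles=(V_288DEL, V_349DEL), events_complete=False,
            events=(_ev("gait_disturbance", 10.0, _SEVERE_GAIT),),
            notes="nephew of XP363BE; detailed event ages in figure only",
        ),
        Patient(
            patient_id="XP631BE", sex="F", family_id="FAM-360",
            reported_class=sev, last_followup_age=10.0,
            alleles=(V_288DEL, V_349DEL), events_complete=False,
            events=(_ev("gait_disturbance", 10.0, _SEVERE_GAIT),),
            notes="niece of XP363BE",
        ),
        Patient(
            patient_id="XP558BE", sex="M", family_id="FAM-558",
            reported_class=sev, last_followup_age=10.0,
            alleles=(V_315, V_324), events_complete=False,
            events=(_ev("gait_disturbance", 10.0, _SEVERE_GAIT),),
            notes=_SEX_AGG,
        ),
        Patient(
            patient_id="XP336BE", sex="M", family_id="FAM-336",
            reported_class=sev, last_followup_age=10.0,
            alleles=(V_338DEL, V_603DEL), events_complete=False,
            events=(_ev("gait_disturbance", 10.0, _SEVERE_GAIT),),
            notes=_SEX_AGG,
        ),
        Patient(
            patient_id="XP120BE", sex="F", family_id="FAM-120",
            reported_class=sev, last_followup_age=10.0,
            alleles=(V_E111X, V_E111X), events_complete=False,
            events=(_ev("gait_disturbance", 10.0, _SEVERE_GAIT),),
            notes="zygosity inferred: only p.Glu111* reported; " + _SEX_AGG,
        ),
        Patient(
            patient_id="XP40BE", sex="M", family_id="FAM-40",
            reported_class=sev, last_followup_age=10.0,
            alleles=(V_Q216X,), hemizygous=True, events_complete=False,
            events=(_ev("gait_disturbance", 10.0, _SEVERE_GAIT),),
            notes="hemizygous p.Gln216*; " + _SEX_AGG,
        ),
        Patient(
            patient_id="XP509BE", sex="M", family_id="FAM-509",
            reported_class=sev, last_followup_age=10.0,
            alleles=(V_Q216X,), hemizygous=True, events_complete=False,
            events=(_ev("gait_disturbance", 10.0, _SEVERE_GAIT),),
            notes="hemizygous p.Gln216*; " + _SEX_AGG,
        ),
        # ---- intermediate group (n = 5) -------------------------------
        Patient(
            patient_id="XP12BE", sex="F", family_id="FAM-12",
            reported_class=inter, death_age=44.0, death_neurologic=True,
            last_followup_age=44.0,
            alleles=(V_390AC, V_555GC),
            events=(
                _ev("hyporeflexia_only", 7.0,
                    "at age 7 areflexia; tandem-walk difficulty not scored "
                    "as gait disturbance (age-10 score -1)"),
                _ev("hearing_mild", 17.0,
                    "by 17 mild bilateral hearing loss, 4F-PTA 26.25 dBHL, "
                    "fitted with hearing aids", pta=26.25),
                _ev("peripheral_neuropathy", 21.0,
                    "at 21 nerve conduction showed sensory-motor peripheral "
                    "neuropathy"),
                _ev("gait_disturbance", 24.0,
                    "by 24 cerebellar dysfunction involving gait"),
                _ev("dysphagia", 36.0, "at 36 mild dysphagia"),
                _ev("g_tube", 37.0,
                    "G-tube placed due to inability to swallow food"),
                _ev("cannot_walk", 41.0, "by 41 non-ambulatory"),
            ),
            notes="died of neurologic degeneration at 44",
        ),
        Patient(
            patient_id="XP19BE", sex="F", family_id="FAM-19",
            reported_class=inter, last_followup_age=33.0,
            alleles=(V_555GC, V_555GC),
            events=(
                _ev("mild_dev_delay", 10.0, _C555_DD),
                _ev("hearing_moderate", 24.0,
                    "moderate hearing loss emerging at age 24"),
                _ev("gait_disturbance", 33.0,
                    "gait disturbance at age 33"),
                _ev("peripheral_neuropathy", 33.0,
                    "axonal sensorimotor polyneuropathy at 33"),
                _ev("dysphagia", 33.0, "dysphagia at age 33"),
            ),
            notes=_SEX_AGG,
        ),
        Patient(
            patient_id="XP79BE", sex="F", family_id="FAM-79",
            reported_class=inter, last_followup_age=33.0,
            alleles=(V_C126W, V_555GC), events_complete=False,
            events=(_ev("mild_dev_delay", 10.0, _C555_DD),),
            notes="gait-disturbance onset between 24 and 33, exact age not "
                  "printed; " + _SEX_AGG,
        ),
        Patient(
            patient_id="XP81BE", sex="F", family_id="FAM-81",
            reported_class=inter, last_followup_age=10.0,
            alleles=(), events_complete=False,
            notes="genotype and event detail in figure only; " + _SEX_AGG,
        ),
        Patient(
            patient_id="XP591BE", sex="F", family_id="FAM-591",
            reported_class=inter, last_followup_age=10.0,
            alleles=(V_R228X, UNKNOWN_ALLELE), events_complete=False,
            notes="second allele not printed; " + _SEX_AGG,
        ),
        # ---- mild group (n = 5) ---------------------------------------
        Patient(
            patient_id="XP53BE", sex="M", family_id="FAM-53",
            reported_class=mild, last_followup_age=40.0,
            alleles=(V_IVS4, V_IVS4),
            events=(),
            notes="normal early milestones; age-10 score 0; self-reported "
                  "no hearing loss, gait disturbance, or other neurological "
                  "symptoms at 40",
        ),
        Patient(
            patient_id="XP618BE", sex="F", family_id="FAM-618",
            reported_class=mild, last_followup_age=10.0,
            alleles=(V_IVS4, V_IVS4), events_complete=False,
            events=(),
            notes="carriers of this founder splice variant score 0 at age "
                  "10; " + _SEX_AGG,
        ),
        Patient(
            patient_id="XP337BE", sex="F", family_id="FAM-337",
            reported_class=mild, last_followup_age=31.0,
            alleles=(V_EX6DEL,), hemizygous=True, events_complete=False,
            events=(),
            notes="hemizygous exon-6 genomic deletion; mild clinical "
                  "features at 31",
        ),
        Patient(
            patient_id="XP315BE", sex="F", family_id="FAM-315",
            reported_class=mild, last_followup_age=35.0,
            alleles=(V_349DEL, V_142DEL),
            events=(
                _ev("seizures", 33.0,
                    "seizure disorder beginning at age 33"),
            ),
            notes="normal milestones, lives independently; absent deep "
                  "tendon reflexes with onset age not printed (omitted)",
        ),
        Patient(
            patient_id="XP607BE", sex="M", family_id="FAM-607",
            reported_class=mild, last_followup_age=45.0,
            alleles=(V_555GC, V_R258FS),
            events=(
                _ev("mild_dev_delay", 18.0,
                    "developmental delay (IQ 50-85) at age 18"),
                _ev("gait_disturbance", 37.0,
                    "gait disturbance at age 37"),
                _ev("peripheral_neuropathy", 39.0,
                    "peripheral sensorimotor neuropathy by 39"),
            ),
            notes="oldest patient in the cohort at 45",
        ),
    ]
    return CohortTable(
        patients=patients, variant_ids=frozenset(FIXTURE_VARIANT_IDS)
    )


def reported_classes(cohort: CohortTable | None = None) -> dict[str, str]:
    """Clinically reported severity group per patient id."""
    cohort = cohort or fixture_cohort()
    return {
        p.patient_id: p.reported_class
        for p in cohort.patients
        if p.reported_class is not None
    }
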