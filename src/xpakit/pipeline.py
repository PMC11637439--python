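"""Pipeline orchestration: compose scoring, classification, variant
rules, diplotype prediction, carriers-based variant labels, and the
survival analyses into a deterministic report bundle (plain TSV + JSON).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import scale, survival, variants as va
from .cohort import CohortTable
from .variants import DEFAULT_GENE_MAP, GeneMap

log = logging.getLogger("xpakit")

ONSET_FEATURES_DEFAULT = (
    "gait_disturbance",
    "peripheral_neuropathy",
    "dysphagia",
)


@dataclass(frozen=True)
class PipelineConfig:
    evaluation_age: float = 10.0
    mild_threshold: float = scale.MILD_THRESHOLD
    genemap: GeneMap = DEFAULT_GENE_MAP
    median_averaging: bool = True
    neurologic_death_only: bool = False
    onset_features: tuple[str, ...] = ONSET_FEATURES_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-4.3 <= self.mild_threshold <= 0):
            raise ValueError("mild_threshold outside the score range")
        if self.evaluation_age < 0:
            raise ValueError("evaluation_age must be >= 0")


def clinical_classes(
    cohort: CohortTable, evaluation_age: float = 10.0
) -> dict[str, str]:
    """Clinical severity class per patient: the scale applied at the
    evaluation age where the event record is complete, falling back to
    the reported severity group where event detail is only partly
    known."""
    scored = scale.classify_cohort(cohort, evaluation_age)
    out: dict[str, str] = {}
    for p in cohort.patients:
        if not p.events_complete and p.reported_class is not None:
            out[p.patient_id] = p.reported_class
        else:
            out[p.patient_id] = scored[p.patient_id]
    return out


def run_pipeline(
    cohort: CohortTable,
    variant_records: dict[str, va.VariantRecord] | None,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> dict:
    """Run every stage over a cohort and optional variant table.

    Returns the report bundle as a dict; when ``out_dir`` is given, also
    writes ``scores.tsv``, ``predictions.tsv``, ``variants.tsv``,
    ``onset_<feature>.tsv``, ``survival.tsv`` and ``report.json``
    (byte-identical across runs for the same inputs and config).
    """
    log.info(
        "pipeline: evaluation_age=%s mild_threshold=%s exons=%s",
        config.evaluation_age,
        config.mild_threshold,
        config.genemap.exons,
    )
    report: dict = {
        "config": {
            "evaluation_age": config.evaluation_age,
            "mild_threshold": config.mild_threshold,
            "exon_table": [list(e) for e in config.genemap.exons],
            "median_averaging": config.median_averaging,
            "neurologic_death_only": config.neurologic_death_only,
            "seed": config.seed,
        }
    }

    # --- per-patient scores and classes -------------------------------
    score_rows = []
    for p in cohort.patients:
        prof = scale.profile_at_age(p, config.evaluation_age)
        sc = scale.score_profile(prof)
        score_rows.append(
            {
                "patient_id": p.patient_id,
                "evaluation_age": config.evaluation_age,
                "major_component": sc.major_component,
                "minor_count": sc.minor_count,
                "total": sc.total,
                "scale_class": scale.classify(sc),
                "contributions": json.dumps(
                    scale.feature_contributions(prof), sort_keys=True
                ),
            }
        )
    classes = clinical_classes(cohort, config.evaluation_age)
    report["classes"] = classes
    report["scores"] = {
        r["patient_id"]: r["total"] for r in score_rows
    }

    # --- variant annotation, rules, diplotypes, carrier labels --------
    variant_rows = []
    prediction_rows = []
    if variant_records:
        carrier_labels = va.variant_severity_from_carriers(cohort, classes)
        for vid, rec in variant_records.items():
            loc = va.locate(rec, config.genemap)
            sev = va.allele_severity_rules(rec, config.genemap)
            variant_rows.append(
                {
                    "identifier": vid,
                    "consequence": rec.consequence,
                    "region": loc.region,
                    "domain": loc.domain or ".",
                    "rule_id": sev.rule_id,
                    "rule_label": sev.label,
                    "carriers_label": carrier_labels.get(vid, "."),
                }
            )
        predictions = va.predict_cohort(
            cohort, variant_records, config.genemap
        )
        for pid, pred in predictions.items():
            clinical = classes.get(pid, ".")
            prediction_rows.append(
                {
                    "patient_id": pid,
                    "predicted_class": pred.label,
                    "low_confidence": pred.low_confidence,
                    "clinical_class": clinical,
                    "agreement": pred.label == clinical,
                }
            )
        report["variant_rule_labels"] = {
            r["identifier"]: r["rule_label"] for r in variant_rows
        }
        report["variant_carrier_labels"] = {
            r["identifier"]: r["carriers_label"] for r in variant_rows
        }
        report["diplotype_predictions"] = {
            r["patient_id"]: r["predicted_class"] for r in prediction_rows
        }

    # --- survival analyses --------------------------------------------
    onset_tables: dict[str, pd.DataFrame] = {}
    report["onset"] = {}
    if cohort.patients:
        for feature in config.onset_features:
            res = survival.onset_analysis(
                cohort, feature, classes, averaging=config.median_averaging
            )
            rows = []
            for g in sorted(res.curves):
                c = res.curves[g]
                for t, s, n, d in zip(
                    c.times, c.survival, c.at_risk, c.events
                ):
                    rows.append(
                        {
                            "group": g,
                            "time": t,
                            "at_risk": n,
                            "events": d,
                            "survival": round(float(s), 10),
                        }
                    )
            onset_tables[feature] = pd.DataFrame(
                rows, columns=["group", "time", "at_risk", "events",
                               "survival"]
            )
            report["onset"][feature] = {
                "medians": {
                    g: res.medians[g] for g in sorted(res.medians)
                },
                "n": {g: res.n_per_group[g] for g in sorted(res.n_per_group)},
                "logrank": (
                    {
                        "chi2": round(res.logrank.chi2, 10),
                        "df": res.logrank.df,
                        "p": round(res.logrank.p, 12),
                    }
                    if res.logrank
                    else None
                ),
            }
        mort = survival.mortality_analysis(
            cohort,
            classes,
            neurologic_only=config.neurologic_death_only,
            averaging=config.median_averaging,
        )
        mort_rows = []
        for g in sorted(mort.curves):
            c = mort.curves[g]
            for t, s, n, d in zip(c.times, c.survival, c.at_risk, c.events):
                mort_rows.append(
                    {
                        "group": g,
                        "time": t,
                        "at_risk": n,
                        "events": d,
                        "survival": round(float(s), 10),
                    }
                )
        mort_table = pd.DataFrame(
            mort_rows,
            columns=["group", "time", "at_risk", "events", "survival"],
        )
        report["survival"] = {
            "medians": {g: mort.medians[g] for g in sorted(mort.medians)},
            "logrank": (
                {
                    "chi2": round(mort.logrank.chi2, 10),
                    "df": mort.logrank.df,
                    "p": round(mort.logrank.p, 12),
                }
                if mort.logrank
                else None
            ),
        }
    else:
        mort_table = pd.DataFrame(
            columns=["group", "time", "at_risk", "events", "survival"]
        )
        report["survival"] = {"medians": {}, "logrank": None}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            score_rows,
            columns=[
                "patient_id", "evaluation_age", "major_component",
                "minor_count", "total", "scale_class", "contributions",
            ],
        ).to_csv(out / "scores.tsv", sep="\t", index=False)
        pd.DataFrame(
            prediction_rows,
            columns=[
                "patient_id", "predicted_class", "low_confidence",
                "clinical_class", "agreement",
            ],
        ).to_csv(out / "predictions.tsv", sep="\t", index=False)
        pd.DataFrame(
            variant_rows,
            columns=[
                "identifier", "consequence", "region", "domain", "rule_id",
                "rule_label", "carriers_label",
            ],
        ).to_csv(out / "variants.tsv", sep="\t", index=False)
        for feature, table in onset_tables.items():
            table.to_csv(out / f"onset_{feature}.tsv", sep="\t", index=False)
        mort_table.to_csv(out / "survival.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
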