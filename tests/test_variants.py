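import pytest

from xpakit import variants as va
from xpakit.pipeline import clinical_classes
from xpakit.variants import (
    DEFAULT_GENE_MAP,
    AlleleSeverity,
    GeneMap,
    VariantParseError,
    allele_severity_rules,
    diplotype_severity,
    locate,
    parse_variant,
    variant_severity_from_carriers,
)


class TestParse:
    def test_nonsense_with_coding_change(self):
        rec = parse_variant("c.315C>A, p.Cys105*")
        assert rec.consequence == "nonsense"
        assert rec.protein_pos == 105
        assert rec.truncating

    def test_intronic_donor_region_substitution(self):
        rec = parse_variant("c.555+8A>G")
        assert rec.consequence == "splice_donor_region"
        assert rec.cdna_pos == 555 and rec.intron_offset == 8
        assert locate(rec).region == "intron 4"

    def test_ivs_notation_normalises_to_coding_offsets(self):
        a = parse_variant("IVS4+8A>G")
        b = parse_variant("c.555+8A>G")
        assert (a.cdna_pos, a.intron_offset, a.ref, a.alt, a.consequence) == (
            b.cdna_pos, b.intron_offset, b.ref, b.alt, b.consequence
        )

    def test_whole_exon_deletion(self):
        rec = parse_variant("c.674_819del")
        assert rec.consequence == "genomic_deletion"
        assert (rec.cdna_pos, rec.cdna_end) == (674, 819)
        assert rec.truncating

    def test_frameshift_protein_notation(self):
        rec = parse_variant("p.Arg258Tyrfs*5")
        assert rec.consequence == "frameshift"
        assert rec.protein_pos == 258

    def test_unparseable_token_reported(self):
        with pytest.raises(VariantParseError, match="c.10banana"):
            parse_variant("c.10banana")


class TestLocate:
    @pytest.mark.parametrize(
        "raw,region,domain",
        [
            ("p.Gln216*", "exon 5", "DNA-binding"),
            ("c.142delT, p.Tyr48Thrfs*15", "exon 1", "N-terminal disordered"),
            ("p.Arg258Tyrfs*5", "exon 6", "C-terminal"),
            ("c.390-1G>T", "intron 3", None),
        ],
    )
    def test_region_and_domain(self, raw, region, domain):
        loc = locate(parse_variant(raw))
        assert loc.region == region
        assert loc.domain == domain

    def test_c555_is_last_base_of_exon_4(self):
        assert DEFAULT_GENE_MAP.exon_of(555) == 4
        assert DEFAULT_GENE_MAP.exon_end(4) == 555

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            DEFAULT_GENE_MAP.exon_of(820)

    def test_bad_exon_table_rejected(self):
        with pytest.raises(ValueError):
            GeneMap(exons=((1, 100), (102, 819)))

    def test_genemap_json_round_trip(self, tmp_path):
        path = tmp_path / "genemap.json"
        DEFAULT_GENE_MAP.to_json(path)
        assert GeneMap.from_json(path) == DEFAULT_GENE_MAP


EXPECTED_RULE_LABELS = {
    "c.288delT": "severe",
    "c.349_353delCTTAT": "severe",
    "c.315C>A": "severe",
    "c.324T>A": "severe",
    "c.338_339delTG": "severe",
    "c.603_607delAGAAG": "severe",
    "p.Glu111*": "severe",
    "p.Gln216*": "severe",
    "c.555G>C": "intermediate",
    "c.390-1G>T": "severe",
    "p.Cys126Trp": "severe",
    "p.Arg228*": "intermediate",
    "c.555+8A>G": "mild",
    "c.674_819del": "mild",
    "c.142delT": "mild",
    "p.Arg258Tyrfs*5": "mild",
}


class TestRules:
    def test_rule_table_on_all_printed_variants(self, variant_table):
        got = {
            vid: allele_severity_rules(rec).label
            for vid, rec in variant_table.items()
        }
        assert got == EXPECTED_RULE_LABELS

    def test_rule_table_is_total_on_fixture(self, variant_table):
        for rec in variant_table.values():
            assert allele_severity_rules(rec).label != "unknown"

    def test_exon6_override_beats_positional_rule(self):
        # p.Arg228* is an exon-6 truncation, but is intermediate by the
        # explicit override, not mild via the exon-6 rule
        sev = allele_severity_rules(parse_variant("p.Arg228*"))
        assert sev.rule_id.startswith("R5")

    def test_variant_outside_rules_reports_unknown(self):
        # an exon-2 nonsense matches no rule
        sev = allele_severity_rules(parse_variant("p.Gln80*"))
        assert sev.label == "unknown"


class TestDiplotype:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("severe", "mild", "mild"),
            ("intermediate", "mild", "mild"),
            ("severe", "severe", "severe"),
            ("severe", "intermediate", "intermediate"),
        ],
    )
    def test_milder_allele_wins(self, a, b, expected):
        assert diplotype_severity(a, b).label == expected
        assert diplotype_severity(b, a).label == expected  # commutative

    def test_idempotent(self):
        for label in ("mild", "intermediate", "severe"):
            assert diplotype_severity(label, label).label == label

    def test_single_allele_genotype(self):
        assert diplotype_severity("severe").label == "severe"

    def test_unknown_partner_falls_back_with_low_confidence(self):
        pred = diplotype_severity("intermediate", "unknown")
        assert pred.label == "intermediate" and pred.low_confidence

    def test_two_unknown_alleles_rejected(self):
        with pytest.raises(ValueError):
            diplotype_severity("unknown", "unknown")

    def test_accepts_allele_severity_objects(self):
        a = AlleleSeverity("severe", "R1")
        b = AlleleSeverity("mild", "R8")
        assert diplotype_severity(a, b).label == "mild"


class TestCohortPredictions:
    def test_predictions_match_clinical_classes_for_genotyped_patients(
        self, cohort, variant_table
    ):
        classes = clinical_classes(cohort)
        preds = va.predict_cohort(cohort, variant_table)
        assert len(preds) == 17  # one patient is ungenotyped
        for pid, pred in preds.items():
            assert pred.label == classes[pid], pid

    def test_predicted_group_sizes(self, cohort, variant_table):
        preds = va.predict_cohort(cohort, variant_table)
        labels = [p.label for p in preds.values()]
        assert labels.count("severe") == 8
        assert labels.count("mild") == 5
        assert labels.count("intermediate") == 4

    def test_compound_heterozygote_masking(self, cohort, variant_table):
        # the exon-3 frameshift shared with three severe relatives is
        # masked by the exon-1 re-initiation allele
        preds = va.predict_cohort(cohort, variant_table)
        assert preds["XP315BE"].label == "mild"
        assert preds["XP360BE"].label == "severe"


class TestCarrierLabels:
    def test_most_severe_carrier_defines_the_label(self, cohort, variant_table):
        classes = clinical_classes(cohort)
        labels = variant_severity_from_carriers(cohort, classes)
        assert labels["c.349_353delCTTAT"] == "severe"  # mild carrier masked
        assert labels["c.555G>C"] == "intermediate"     # mild carrier masked
        assert labels["c.555+8A>G"] == "mild"

    def test_label_counts_over_printed_variants(self, cohort, variant_table):
        classes = clinical_classes(cohort)
        labels = variant_severity_from_carriers(cohort, classes)
        assert len(labels) == 16
        counts = {
            s: sum(v == s for v in labels.values())
            for s in ("severe", "intermediate", "mild")
        }
        assert counts["severe"] == 8
        assert counts["mild"] == 4

    def test_carrier_label_never_more_severe_than_rule_label(
        self, cohort, variant_table
    ):
        # a milder partner allele can only soften the observed phenotype
        classes = clinical_classes(cohort)
        carrier = variant_severity_from_carriers(cohort, classes)
        for vid, rec in variant_table.items():
            rule = allele_severity_rules(rec).label
            assert (
                va.SEVERITY_ORDER[carrier[vid]] <= va.SEVERITY_ORDER[rule]
            ), vid
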