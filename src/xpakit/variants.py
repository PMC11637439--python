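"""HGVS-like *XPA* variant parsing, exon/domain mapping, and the
mechanistic severity rules.

The gene model is the 273-codon, 6-exon *XPA* coding sequence
(c.1-c.819). Exon boundaries in coding coordinates are configurable
(they are anchored by published landmarks — c.555 is the last base of
exon 4, c.674 the first of exon 6, codon 59 lies in exon 2 — but the
exon 1/2 boundary is not itself a landmark), with domains: disordered
N-terminus aa 1-97, DNA-binding core aa 98-239, C-terminus aa 240-273.

Allele-severity rules (applied in priority order, first match wins):

R1  truncating (nonsense/frameshift) anchored in exon 3 or exon 5 -> severe
R2  missense in exon 3 -> severe
R3  intron-3 splice-acceptor substitution (c.390-1) -> severe
R4  substitution at the last base of exon 4 (c.555G>C) -> intermediate
R5  p.Arg228* -> intermediate (explicit per-variant override: a
    C-terminal truncation with residual activity)
R6  intron-4 donor-region substitution at +8 (creates a new donor) -> mild
R7  truncating in exon 1 upstream of codon 59 (translation
    re-initiation candidate) -> mild
R8  truncating or deletion confined to exon 6 -> mild

A patient's predicted phenotype is the *milder* of the two allele
labels (both alleles contribute, and a milder allele with residual
function dominates the clinical picture).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from .cohort import UNKNOWN_ALLELE, CohortTable

CONSEQUENCES = (
    "nonsense",
    "frameshift",
    "missense",
    "splice_acceptor",
    "splice_donor_region",
    "genomic_deletion",
)

MILD, INTERMEDIATE, SEVERE, UNKNOWN = (
    "mild",
    "intermediate",
    "severe",
    "unknown",
)
#: ordering used by the milder-allele rule
SEVERITY_ORDER = {MILD: 0, INTERMEDIATE: 1, SEVERE: 2}

AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneMap:
    """Exon boundaries (coding coordinates) and protein domains."""

    exons: tuple[tuple[int, int], ...] = (
        (1, 155),
        (156, 282),
        (283, 389),
        (390, 555),
        (556, 673),
        (674, 819),
    )
    domains: tuple[tuple[int, int, str], ...] = (
        (1, 97, "N-terminal disordered"),
        (98, 239, "DNA-binding"),
        (240, 273, "C-terminal"),
    )
    n_codons: int = 273

    def __post_init__(self) -> None:
        pos = 1
        for start, end in self.exons:
            if start != pos or end < start:
                raise ValueError(
                    "exons must be contiguous, non-overlapping, and cover "
                    "the coding sequence"
                )
            pos = end + 1
        if pos - 1 != 3 * self.n_codons:
            raise ValueError(
                f"exons cover c.1-{pos - 1}, expected {3 * self.n_codons}"
            )

    @property
    def cds_length(self) -> int:
        return self.exons[-1][1]

    def exon_of(self, cdna_pos: int) -> int:
        """1-based exon number containing a coding position."""
        if not (1 <= cdna_pos <= self.cds_length):
            raise ValueError(f"c.{cdna_pos} outside c.1-{self.cds_length}")
        for i, (start, end) in enumerate(self.exons, start=1):
            if start <= cdna_pos <= end:
                return i
        raise AssertionError  # unreachable

    def exon_end(self, exon: int) -> int:
        return self.exons[exon - 1][1]

    def domain_of(self, codon: int) -> str:
        for lo, hi, name in self.domains:
            if lo <= codon <= hi:
                return name
        raise ValueError(f"codon {codon} outside 1-{self.n_codons}")

    @classmethod
    def from_json(cls, path) -> "GeneMap":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(
            exons=tuple(tuple(e) for e in cfg["exons"]),
            domains=tuple(tuple(d) for d in cfg["domains"]),
            n_codons=cfg.get("n_codons", 273),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "exons": [list(e) for e in self.exons],
                    "domains": [list(d) for d in self.domains],
                    "n_codons": self.n_codons,
                },
                fh,
                indent=1,
            )


DEFAULT_GENE_MAP = GeneMap()


@dataclass(frozen=True)
class VariantRecord:
    raw: str
    consequence: str
    cdna_pos: int | None = None          # anchor coding position
    cdna_end: int | None = None          # end of a deleted range
    intron_offset: int | None = None     # signed offset for intronic changes
    protein_pos: int | None = None       # affected codon, when derivable
    ref: str | None = None
    alt: str | None = None
    truncating: bool = False

    @property
    def identifier(self) -> str:
        return canonical_id(self.raw)

    @property
    def intronic(self) -> bool:
        return self.intron_offset is not None and self.intron_offset != 0


def canonical_id(raw: str) -> str:
    """Canonical identifier: the first printed token (c. preferred)."""
    return raw.split(",")[0].strip()


_C_SUB = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_C_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")
_P_NONSENSE = re.compile(r"^p\.([A-Z][a-z]{2}|[A-Z])(\d+)(\*|Ter)$")
_P_FS = re.compile(
    r"^p\.([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])fs\*?(\d+)?$"
)
_P_MISSENSE = re.compile(r"^p\.([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])$")
_IVS = re.compile(r"^IVS(\d+)([+-]\d+)([ACGT])>([ACGT])$")

#: deletions at least this long, or covering a whole exon, count as
#: genomic deletions rather than small indels
GENOMIC_DELETION_MIN = 50


def _codon_to_cdna(codon: int) -> int:
    return 3 * codon - 2


def parse_variant(raw: str, genemap: GeneMap = DEFAULT_GENE_MAP) -> VariantRecord:
    """Parse an HGVS-like variant string.

    Accepts single tokens (``c.555G>C``, ``c.142delT``, ``p.Gln216*``,
    ``p.Arg258Tyrfs*5``, ``IVS4+8A>G``, ``c.674_819del``) or a printed
    pair ``"c.315C>A, p.Cys105*"``. IVS notation is normalised to
    c. intron-offset form using the exon table (IVS4+8 = c.555+8).
    """
    raw = raw.strip()
    tokens = [t.strip() for t in raw.split(",") if t.strip()]
    if not tokens:
        raise VariantParseError("empty variant string")

    cdna_pos = cdna_end = intron_offset = protein_pos = None
    ref = alt = None
    consequence = None
    truncating = False

    for tok in tokens:
        m = _IVS.match(tok)
        if m:
            intron, off = int(m.group(1)), int(m.group(2))
            anchor = (
                genemap.exon_end(intron)
                if off > 0
                else genemap.exon_end(intron) + 1  # start of next exon
            )
            cdna_pos = anchor
            intron_offset = off
            ref, alt = m.group(3), m.group(4)
            consequence = (
                "splice_donor_region" if off > 0 else "splice_acceptor"
            )
            continue
        m = _C_SUB.match(tok)
        if m:
            cdna_pos = int(m.group(1))
            intron_offset = int(m.group(2)) if m.group(2) else None
            ref, alt = m.group(3), m.group(4)
            if intron_offset is not None:
                consequence = (
                    "splice_donor_region"
                    if intron_offset > 0
                    else "splice_acceptor"
                )
            elif cdna_pos == genemap.exon_end(genemap.exon_of(cdna_pos)):
                # substitution at an exon's last base hits the donor region
                consequence = "splice_donor_region"
            elif consequence is None:
                consequence = "missense"
            continue
        m = _C_DEL.match(tok)
        if m:
            cdna_pos = int(m.group(1))
            cdna_end = int(m.group(2)) if m.group(2) else cdna_pos
            length = cdna_end - cdna_pos + 1
            covers_exon = any(
                cdna_pos <= s and e <= cdna_end for s, e in genemap.exons
            )
            if length >= GENOMIC_DELETION_MIN or covers_exon:
                consequence = "genomic_deletion"
            else:
                consequence = "frameshift" if length % 3 else consequence
            truncating = True
            continue
        m = _P_NONSENSE.match(tok)
        if m:
            protein_pos = int(m.group(2))
            if consequence in (None, "missense"):
                consequence = "nonsense"
            truncating = True
            continue
        m = _P_FS.match(tok)
        if m:
            protein_pos = int(m.group(2))
            if consequence in (None, "missense", "frameshift"):
                consequence = "frameshift"
            truncating = True
            continue
        m = _P_MISSENSE.match(tok)
        if m:
            protein_pos = int(m.group(2))
            if consequence is None:
                consequence = "missense"
            continue
        raise VariantParseError(f"unparseable variant token: {tok!r}")

    if consequence is None:
        raise VariantParseError(f"could not infer consequence for {raw!r}")
    if consequence in ("nonsense", "frameshift"):
        truncating = True
    if cdna_pos is None and protein_pos is not None:
        cdna_pos = _codon_to_cdna(protein_pos)
    if protein_pos is None and cdna_pos is not None and intron_offset is None:
        protein_pos = (cdna_pos + 2) // 3
    return VariantRecord(
        raw=raw,
        consequence=consequence,
        cdna_pos=cdna_pos,
        cdna_end=cdna_end,
        intron_offset=intron_offset,
        protein_pos=protein_pos,
        ref=ref,
        alt=alt,
        truncating=truncating,
    )


@dataclass(frozen=True)
class Location:
    region: str          # "exon k" or "intron k"
    exon: int | None
    intron: int | None
    domain: str | None


def locate(record: VariantRecord, genemap: GeneMap = DEFAULT_GENE_MAP) -> Location:
    """Place a parsed variant on the exon/intron map and protein domains."""
    if record.cdna_pos is None:
        raise ValueError(f"{record.raw}: no coding anchor to locate")
    anchor_exon = genemap.exon_of(record.cdna_pos)
    if record.intronic:
        # intron k follows exon k for +offsets, precedes exon k for -offsets
        intron = anchor_exon if record.intron_offset > 0 else anchor_exon - 1
        return Location(
            region=f"intron {intron}", exon=None, intron=intron, domain=None
        )
    domain = (
        genemap.domain_of(record.protein_pos)
        if record.protein_pos is not None
        else None
    )
    return Location(
        region=f"exon {anchor_exon}",
        exon=anchor_exon,
        intron=None,
        domain=domain,
    )


@dataclass(frozen=True)
class AlleleSeverity:
    label: str
    rule_id: str

    def __post_init__(self) -> None:
        if self.label != UNKNOWN and self.label not in SEVERITY_ORDER:
            raise ValueError(f"bad severity label {self.label!r}")


def allele_severity_rules(
    record: VariantRecord, genemap: GeneMap = DEFAULT_GENE_MAP
) -> AlleleSeverity:
    """Apply the mechanistic rules R1-R8 (first match wins)."""
    loc = locate(record, genemap)

    if record.truncating and loc.exon in (3, 5):
        return AlleleSeverity(SEVERE, f"R1:truncating-{loc.region}")
    if record.consequence == "missense" and loc.exon == 3:
        return AlleleSeverity(SEVERE, "R2:missense-exon-3")
    if (
        record.consequence == "splice_acceptor"
        and loc.intron == 3
    ):
        return AlleleSeverity(SEVERE, "R3:intron-3-acceptor")
    if (
        record.consequence == "splice_donor_region"
        and not record.intronic
        and record.cdna_pos == genemap.exon_end(4)
    ):
        return AlleleSeverity(INTERMEDIATE, "R4:exon-4-last-base")
    if record.consequence == "nonsense" and record.protein_pos == 228:
        return AlleleSeverity(INTERMEDIATE, "R5:p.Arg228*-override")
    if (
        record.consequence == "splice_donor_region"
        and loc.intron == 4
        and record.intron_offset == 8
    ):
        return AlleleSeverity(MILD, "R6:intron-4+8-new-donor")
    if (
        record.truncating
        and loc.exon == 1
        and record.protein_pos is not None
        and record.protein_pos < 59
    ):
        return AlleleSeverity(MILD, "R7:exon-1-reinitiation")
    if record.truncating and loc.exon == 6:
        return AlleleSeverity(MILD, "R8:exon-6-truncation")
    return AlleleSeverity(UNKNOWN, "none")


@dataclass(frozen=True)
class DiplotypePrediction:
    label: str
    low_confidence: bool = False


def diplotype_severity(
    a1: AlleleSeverity | str | None, a2: AlleleSeverity | str | None = None
) -> DiplotypePrediction:
    """Milder-allele rule: the predicted phenotype is the milder of the
    two allele labels; a single (hemizygous/homozygous-collapsed) allele
    predicts its own label; one unknown allele falls back to the known
    label at low confidence."""

    def label_of(a):
        if a is None:
            return None
        if isinstance(a, AlleleSeverity):
            return None if a.label == UNKNOWN else a.label
        return None if a in (UNKNOWN, UNKNOWN_ALLELE) else a

    l1, l2 = label_of(a1), label_of(a2)
    known = [x for x in (l1, l2) if x is not None]
    if not known:
        raise ValueError("diplotype_severity requires at least one known allele")
    label = min(known, key=SEVERITY_ORDER.__getitem__)
    both_supplied = a1 is not None and a2 is not None
    return DiplotypePrediction(
        label=label, low_confidence=both_supplied and len(known) < 2
    )


def predict_cohort(
    cohort: CohortTable,
    variants: dict[str, VariantRecord],
    genemap: GeneMap = DEFAULT_GENE_MAP,
) -> dict[str, DiplotypePrediction]:
    """Rules + milder-allele diplotype prediction for every genotyped
    patient. Ungenotyped patients are omitted."""
    allele_labels = {
        vid: allele_severity_rules(rec, genemap)
        for vid, rec in variants.items()
    }
    out: dict[str, DiplotypePrediction] = {}
    for p in cohort.patients:
        if not p.genotyped:
            continue
        labels = [
            allele_labels[a] if a != UNKNOWN_ALLELE else None
            for a in p.alleles
        ]
        if len(labels) == 1:
            out[p.patient_id] = diplotype_severity(labels[0])
        else:
            out[p.patient_id] = diplotype_severity(labels[0], labels[1])
    return out


def variant_severity_from_carriers(
    cohort: CohortTable, classes: dict[str, str]
) -> dict[str, str]:
    """Label each variant with the *most severe* clinical class among its
    carriers (a severe allele masked by a milder partner in one carrier
    still labels severe). Variants with no genotyped carrier are omitted."""
    out: dict[str, str] = {}
    for p in cohort.patients:
        cls = classes.get(p.patient_id)
        if cls not in SEVERITY_ORDER:
            continue
        for a in set(p.alleles):
            if a == UNKNOWN_ALLELE:
                continue
            if a not in out or SEVERITY_ORDER[cls] > SEVERITY_ORDER[out[a]]:
                out[a] = cls
    return out


def fixture_variants(
    genemap: GeneMap = DEFAULT_GENE_MAP,
) -> dict[str, VariantRecord]:
    """The 16 variants printed in the study text, keyed by canonical id."""
    printed = [
        "c.288delT, p.Val97Leufs*7",
        "c.349_353delCTTAT, p.Leu117Glufs*4",
        "c.315C>A, p.Cys105*",
        "c.324T>A, p.Cys108*",
        "c.338_339delTG, p.Met113Argfs*9",
        "c.603_607delAGAAG, p.Glu201Aspfs*18",
        "p.Glu111*",
        "p.Gln216*",
        "c.555G>C, p.Gln185His",
        "c.390-1G>T",
        "p.Cys126Trp",
        "p.Arg228*",
        "c.555+8A>G",
        "c.674_819del, p.Glu225Valfs*4",
        "c.142delT, p.Tyr48Thrfs*15",
        "p.Arg258Tyrfs*5",
    ]
    return {canonical_id(s): parse_variant(s, genemap) for s in printed}
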