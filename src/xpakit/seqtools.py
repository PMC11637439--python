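"""Splice-donor individual-information scoring and in-silico
restriction digestion.

Donor sites are scored over a 9-base window spanning positions -3..+6
around the exon/intron boundary. From aligned training donors with
frequency ``f(b, l)`` (pseudocount-smoothed), the weight of base ``b``
at window position ``l`` is::

    w(b, l) = 2 + log2 f(b, l)     [bits, uniform background]

and a candidate window scores the sum of its per-position weights
(individual information, Ri). The ceiling is 2 bits per position, so a
9-base window tops out just below 18 bits under an invariant training
set. The packaged default matrix is built from a small bundled training
fixture and is *not* a canonical genome-wide donor model.

Restriction digestion models an enzyme as a (recognition motif, cut
offset) pair; every motif occurrence — including overlapping ones — is
cut, and fragments between successive cut positions always sum to the
sequence length. Tsp509I is motif ``AATT`` cut at offset 0 (5' of the
motif).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

WINDOW = 9          # donor footprint: -3..-1 exonic, +1..+6 intronic
EXONIC_PART = 3     # bases of the window upstream of the boundary

#: small bundled donor training set (synthetic consensus-like donors;
#: not derived from any genome-scale alignment)
DEFAULT_TRAINING = (
    "CAGGTAAGT",
    "AAGGTAAGT",
    "CAGGTGAGT",
    "CAGGTAAGA",
    "AAGGTGAGT",
    "CGGGTAAGT",
)


def _validate_seq(seq: str, label: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"{label} contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class DonorMatrix:
    """Per-position nucleotide weights in bits, columns -3..+6."""

    weights: tuple[tuple[float, ...], ...]  # WINDOW x 4, A/C/G/T order

    def __post_init__(self) -> None:
        if len(self.weights) != WINDOW or any(
            len(row) != 4 for row in self.weights
        ):
            raise ValueError(f"weights must be {WINDOW} positions x 4 bases")

    @property
    def max_score(self) -> float:
        return float(sum(max(row) for row in self.weights))

    @property
    def consensus(self) -> str:
        return "".join(
            BASES[int(np.argmax(row))] for row in self.weights
        )

    def to_json(self, path) -> None:
        payload = {
            str(pos - EXONIC_PART): dict(zip(BASES, row))
            for pos, row in enumerate(self.weights)
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DonorMatrix":
        with open(path) as fh:
            payload = json.load(fh)
        keys = sorted(payload, key=int)
        return cls(
            weights=tuple(
                tuple(payload[k][b] for b in BASES) for k in keys
            )
        )


def build_donor_matrix(
    training, pseudocount: float = 0.25
) -> DonorMatrix:
    """Build an individual-information weight matrix from aligned 9-mer
    donor sequences.

    Frequencies are smoothed with ``pseudocount`` per base per column;
    weights are ``2 + log2 f`` bits against a uniform background.
    """
    training = [
        _validate_seq(s, "training sequence") for s in training
    ]
    if len(training) < 2:
        raise ValueError("need at least 2 training sequences")
    if any(len(s) != WINDOW for s in training):
        raise ValueError(f"training sequences must have length {WINDOW}")
    counts = np.full((WINDOW, 4), float(pseudocount))
    for s in training:
        for pos, base in enumerate(s):
            counts[pos, _BASE_INDEX[base]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    weights = 2.0 + np.log2(freqs)
    return DonorMatrix(weights=tuple(tuple(row) for row in weights))


def default_donor_matrix() -> DonorMatrix:
    return build_donor_matrix(DEFAULT_TRAINING)


@dataclass(frozen=True)
class DonorSiteScore:
    """A scored candidate donor window; ``position`` is the 0-based
    offset of the exon/intron boundary in the query sequence."""

    position: int
    score: float


def score_donor(seq: str, matrix: DonorMatrix) -> float:
    """Individual information (bits) of one 9-mer under the matrix."""
    seq = _validate_seq(seq)
    if len(seq) != WINDOW:
        raise ValueError(f"donor window must have length {WINDOW}")
    return float(
        sum(matrix.weights[i][_BASE_INDEX[b]] for i, b in enumerate(seq))
    )


def scan_donor_sites(seq: str, matrix: DonorMatrix) -> list[DonorSiteScore]:
    """Score every window of the sequence; boundary position is the
    window start plus the exonic part (3)."""
    seq = _validate_seq(seq)
    return [
        DonorSiteScore(
            position=start + EXONIC_PART,
            score=score_donor(seq[start : start + WINDOW], matrix),
        )
        for start in range(len(seq) - WINDOW + 1)
    ]


def scan_new_donors(
    ref: str,
    substitution: tuple[int, str],
    matrix: DonorMatrix,
    threshold: float,
    reference_boundary: int | None = None,
) -> list[DonorSiteScore]:
    """Donor sites *created* (or strengthened across ``threshold``) by a
    single-base substitution.

    A window is reported when the mutant score exceeds ``threshold``
    while the reference score did not; only windows overlapping the
    substitution can change. Positions are boundary offsets, reported
    relative to ``reference_boundary`` when given (e.g. +8 for a new
    donor eight bases downstream of a natural site).
    """
    ref = _validate_seq(ref)
    pos, base = substitution
    base = base.upper()
    if not (0 <= pos < len(ref)):
        raise ValueError(f"substitution position {pos} outside sequence")
    if base not in BASES:
        raise ValueError(f"substitution base must be one of {BASES}")
    mut = ref[:pos] + base + ref[pos + 1 :]

    hits: list[DonorSiteScore] = []
    first = max(0, pos - WINDOW + 1)
    last = min(pos, len(ref) - WINDOW)
    for start in range(first, last + 1):
        ref_score = score_donor(ref[start : start + WINDOW], matrix)
        mut_score = score_donor(mut[start : start + WINDOW], matrix)
        if mut_score > threshold >= ref_score:
            boundary = start + EXONIC_PART
            if reference_boundary is not None:
                boundary -= reference_boundary
            hits.append(DonorSiteScore(position=boundary, score=mut_score))
    return hits


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme as (recognition motif, cut offset within the
    motif: 0 cuts 5' of the first motif base)."""

    motif: str
    cut_offset: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", _validate_seq(self.motif, "motif"))
        if not (0 <= self.cut_offset <= len(self.motif)):
            raise ValueError("cut offset must lie within the motif bounds")


TSP509I = Enzyme(motif="AATT", cut_offset=0, name="Tsp509I")


@dataclass(frozen=True)
class DigestResult:
    fragments: tuple[int, ...]
    cut_positions: tuple[int, ...]


def digest(seq: str, enzyme: Enzyme = TSP509I) -> DigestResult:
    """In-silico digest of a linear sequence.

    All motif occurrences (overlapping included) are cut; fragment
    lengths partition the sequence, so they always sum to its length.
    """
    seq = _validate_seq(seq)
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    cuts = sorted(
        {
            start + enzyme.cut_offset
            for start in range(len(seq) - len(enzyme.motif) + 1)
            if seq.startswith(enzyme.motif, start)
        }
        - {0, len(seq)}  # cuts at the ends do not split anything
    )
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragments=fragments, cut_positions=tuple(cuts))
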