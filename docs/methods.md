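# Methods

## Severity scale

The scale scores a patient's *feature profile* at an evaluation age.
Features are cumulative: once a feature's onset age is passed it stays
active (the disease is progressive; nothing resolves). Hearing-loss
bands (decline without aid / mild / moderate / severe / profound,
keyed on the four-frequency pure-tone average in dBHL) are mutually
exclusive — only the worst active band is retained. Developmental
delay is keyed on IQ bands when an IQ is recorded (50–85 → −1,
35–50 → −2, <35 → −3) and on the clinical token otherwise.

Major features combine by **minimum**, not by sum: the scale describes
the single worst major manifestation, and only the three minor
features (peripheral neuropathy, progressive dysphagia, seizure
history) are additive at −0.1 each. This worst-feature semantics
reproduces all three index-patient scores (−2 with delayed milestones
plus gait disturbance; −1 with hyporeflexia alone; 0 with no
features). Totals therefore live in [−4.3, 0]. Gait precedence needs
no special case — "cannot walk" (−3) supersedes "gait disturbance"
(−2) through the minimum automatically.

Classification bands: only the anchor scores 0 / −1 / ≤−2 are fixed by
the clinical definitions. The mild/intermediate boundary is a declared
constant, −0.75, chosen so that an isolated early-childhood delay
(−0.5) classifies mild while −1 plus any minors stays intermediate.
Death from a non-neurological cause does not score −4; such patients
are censored at death in survival analyses instead.

One encoding ambiguity is preserved rather than resolved: the
intermediate index patient shows ataxic signs (tandem-walk difficulty)
at 8 yet scores −1 at 10, so her qualifying age-10 feature is encoded
as hyporeflexia only; the event's source tag documents the choice.

## Cohort fixture

The packaged cohort is long-format (one event row per feature onset).
Ages are decimal years, rounded to two decimals ("17 months" → 1.42).
Facts available only in figure cells that are not printed in the
running text are encoded as explicit unknowns: one intermediate
patient is ungenotyped, one carries the `unknown` allele sentinel on
the second allele, and patients whose event detail is unprinted are
flagged `events_complete = false` (for the severe group the printed
statement that all eight had gait disturbance by age 10 is encoded as
a single event at 10). Sexes not individually printed are assigned to
reproduce the published totals (10 F / 8 M) and tagged as
aggregate-constrained. Where the event record is incomplete,
`pipeline.clinical_classes` falls back to the reported severity group
rather than scoring an incomplete profile.

## Survival analysis

The Kaplan–Meier estimator, median extraction, and log-rank test are
implemented directly (lifelines appears only as a cross-check oracle
in the tests). Censored observations tied with events at the same time
are counted in the risk set at that time. The median is the smallest
event time with S(t) ≤ 0.5; when the curve sits at exactly 0.5 the
median averages the crossing time with the next event time (a
configuration switch restores the strict convention) — the averaging
convention is needed to produce half-year medians from small
even-sized groups. The log-rank statistic uses the multivariate
hypergeometric variance with the simultaneous-risk-set tie convention,
k−1 degrees of freedom, chi-square upper-tail p, and no continuity
correction. Onset analyses censor feature-free patients at death or
last follow-up and can exclude patients in whom a feature was never
assessed; excluding a patient changes only their own group's curve.
Mortality analysis counts all deaths as events by default, with a
neurologic-death-only switch.

## Variant annotation

Coding coordinates span c.1–819 (273 codons). The default exon table —
e1 c.1–155, e2 156–282, e3 283–389, e4 390–555, e5 556–673,
e6 674–819 — honours the printed anchors (c.142 in exon 1, codon 59 in
exon 2, exon-3 variants within c.283–389, c.390−1 the intron-3
acceptor, c.555 the last base of exon 4, c.674 the first of exon 6);
the exon-1/2 boundary itself is not anchored, so the table is a
configurable object (JSON-loadable), not a hard-coded truth, and rule
reports name the exon used. Protein-only variants are anchored at the
first base of their codon. Intronic positions carry an exon anchor
plus signed offset; IVS notation is normalised against the exon table
(IVS4+8 ≡ c.555+8).

The severity rules fire in priority order R1–R8 (first match wins).
p.Arg228* is an explicit per-variant override (R5, intermediate): it
lies in exon 6 like the mild truncations of R8, but is a
North-African founder allele whose C-terminal truncation retains
partial activity, so a positional rule cannot express it. The
milder-allele diplotype rule uses the declared ordering mild <
intermediate < severe; a genotype with one unknown allele predicts
the known allele's label flagged low-confidence. Two properties tie
the two labelling directions together: rules label alleles by
mechanism, carriers label variants by the *most severe* phenotype
observed, and because partner alleles can only soften phenotypes the
carrier label never exceeds the rule label in severity. On the
packaged fixture the rules plus diplotype reproduce the clinical class
of every genotyped patient, and two variants (the intron-3 acceptor
and the exon-3 missense) are mechanistically severe while their
observed carriers are intermediate — both labels are reported.

## Splice-donor scoring and digestion

Donor windows cover 9 bases (−3..−1 exonic, +1..+6 intronic). Weights
are individual information against a uniform background,
`w(b,l) = 2 + log₂ f(b,l)` with pseudocount-smoothed training
frequencies (default pseudocount 0.25), so each position contributes
at most 2 bits and the consensus maximises the score (verified by
exhaustive 4⁹ enumeration). The packaged default matrix is built from
a small bundled synthetic training set of consensus-like donors and is
explicitly non-canonical: published bit values for specific genomic
sites depend on a training alignment that is not part of this package,
so they are not reproduced here. The window width is a parameter of
the builder rather than a constant of the theory.

`scan_new_donors` reports windows overlapping a substitution whose
score crosses a threshold upward (mutant above, reference at or
below), with positions reported relative to a named natural boundary —
the geometry of a donor-creating intronic change 8 bases downstream of
a weak natural site.

Restriction enzymes are (motif, cut-offset) pairs — no enzyme-database
dependency; Tsp509I is AATT cut at offset 0. All motif occurrences cut,
overlapping ones included; fragments always partition the sequence.
Sequences are uppercased and non-ACGT characters rejected rather than
treated as wildcards.

## Assay metrics

Post-UV survival is modelled single-hit exponential. The default D37
fit is least squares of ln S on dose through the origin (D37 = −1 /
slope); a free-intercept option covers shouldered curves, in which
case D37 is the dose where the fitted line reaches ln S = −1, and the
result records which model was used. Survival fractions above 1 are
clipped with a warning; non-positive fractions are rejected because
the log fit is undefined. UDS and HCR are plain ratios reported as
percent of the normal/unirradiated reference, and a complementation
panel is resolved as the co-transfected gene maximising relative HCR.

## Synthetic data

Generators are pure functions of (config, seed). Cohort onset and
death ages are log-normal — positive support and a direct median
parameterisation, natural when only group medians are known — with the
published per-group medians as defaults (developmental delay 1/5/18
years, gait disturbance 5.5/28/37.5, neuropathy 7/21/39, hearing
11/19/absent, dysphagia 16/24/39; death 22/44.5/none) and group sizes
8/5/5. The common log-scale standard deviation defaults to 0.25,
reflecting the clean between-group separation at age 10 that motivates
the evaluation-age choice; the distribution family and all medians are
configurable. Administrative censoring defaults to age 45 (the oldest
observed patient). The generator emulates group-conditional onset
structure only — it does not model within-family correlation,
measurement error in onset dating, or competing non-neurologic
mortality, so label-recovery results speak to the scale's arithmetic,
not to clinical inter-rater behaviour.

The assay generator multiplies the exact exponential by log-normal
noise. The donor generator plants a weakened consensus at the natural
boundary and a one-mismatch consensus at the target offset, then
resamples the random background until no reference window reaches the
detection threshold (a validity requirement of the planted geometry);
the default threshold sits 2 bits under the matrix maximum.

## Problem sizes and numerical choices

The test suite verifies the survival machinery against lifelines on
200 random datasets (n ≤ 50) at 1e−8–1e−10, log-rank power on 200
simulations of three exponential groups (hazard ratios 1:2:3, 30 per
group), D37 recovery on 100 seeds per planted value, and digestion
conservation on 500 random sequences. Scores are compared exactly
(they are sums of tabled constants rounded to 10 decimals); survival
ties use exact float equality on input times; the log-rank variance
matrix is inverted with a pseudo-inverse so that degenerate risk sets
(all events in one group at the end) remain well-defined.

## Known limitations

The scale encodes one specific clinical scoring convention; published
alternatives with finer gradations are out of scope. The fixture can
only encode facts printed in the running text — figure-only onset ages,
the 18th variant, and one patient's genotype are explicitly unknown,
so cohort-level survival statistics computed from the fixture are
smoke values, not reproductions of the published curves. Genomic
breakpoint discovery (microhomology search) and splice-isoform
structure prediction are out of scope; the sequence tools score donor
windows and fragment lengths only.
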