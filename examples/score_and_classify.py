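"""Score the packaged 18-patient cohort on the neurological severity
scale and classify everyone at age 10.

The total is the worst active major feature (e.g. gait disturbance -2)
minus 0.1 per minor feature; severe <= -2, intermediate in (-2, -0.75],
mild above."""

from xpakit import scale
from xpakit.fixtures import fixture_cohort

cohort = fixture_cohort()
classes = scale.classify_cohort(cohort, evaluation_age=10.0)

print(f"{'patient':9s} {'age-10 total':>12s}  class")
for p in cohort.patients:
    total = scale.score_at_age(p, 10.0).total
    print(f"{p.patient_id:9s} {total:12.1f}  {classes[p.patient_id]}")

print()
print("The three index patients score -2 / -1 / 0, anchoring the severe,")
print("intermediate, and mild bands:")
for pid in ("XP363BE", "XP12BE", "XP53BE"):
    prof = scale.profile_at_age(cohort.patient(pid), 10.0)
    print(f"  {pid}: {scale.feature_contributions(prof) or 'no symptoms'}")
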