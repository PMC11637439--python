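"""In-silico Tsp509I restriction digest of a spliced amplicon.

A 7-base insertion in an abnormal splice isoform creates a new AATT
site: the 166-bp normal amplicon becomes 173 bp and digests into 119-
and 54-bp fragments, while the normal isoform stays uncut."""

from xpakit.seqtools import TSP509I, digest

normal = "G" * 166                       # no AATT site
abnormal = "G" * 119 + "AATT" + "G" * 50   # insertion adds a cut site

for name, seq in (("normal", normal), ("abnormal isoform", abnormal)):
    res = digest(seq, TSP509I)
    print(f"{name:17s} {len(seq)} bp -> fragments {res.fragments}")

print("A heterozygous sample shows all three bands: 166 (uncut normal)")
print("plus 119 and 54 from the isoform carrying the insertion.")
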