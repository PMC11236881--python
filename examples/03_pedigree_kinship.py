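"""Build the numerator relationship matrix A from pedigree records.

A holds expected additive genetic relationships: 0.5 between full sibs,
1 + F on the diagonal (F = inbreeding from related or identical parents).
Stage II uses A as the genotype covariance so related lines share
information.
"""

import metpredict as mp

rows = [
    ("P1", None, None),          # founder
    ("P2", None, None),          # founder
    ("F1a", "P1", "P2"),         # full sibs
    ("F1b", "P1", "P2"),
    ("S1", "F1a", "F1a"),        # selfed progeny of F1a
]
ped = mp.build_pedigree(rows)
A = mp.numerator_relationship(ped)

print("genotypes:", A.genotypes)
print("A matrix:")
for g, row in zip(A.genotypes, A.values):
    print(f"  {g}: " + "  ".join(f"{v:5.3f}" for v in row))
# Full sibs F1a/F1b share 0.5; the selfed line S1 has diagonal 1.5
# (inbreeding coefficient 0.5) and passes 0.75 of F1a's relationships on.
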