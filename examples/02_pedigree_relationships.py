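"""Numerator relationship matrix and inbreeding from a toy pedigree.

A full-sib mating produces an offspring with inbreeding F = 0.25; the A-matrix
diagonal is 1 + F.
"""

import pandas as pd

import wgblup as w

ped = w.Pedigree(
    pd.DataFrame(
        {
            "animal": ["sire", "dam", "sib1", "sib2", "inbred"],
            "sire": [None, None, "sire", "sire", "sib1"],
            "dam": [None, None, "dam", "dam", "sib2"],
        }
    )
)
A = w.build_A(ped)
F = w.inbreeding(ped)

print("A matrix (pedigree order:", ", ".join(A.ids), ")")
print(pd.DataFrame(A.values, index=A.ids, columns=A.ids).round(3))
print()
for animal, f in zip(A.ids, F):
    print(f"F({animal}) = {f:.3f}")
print()
print("sib1/sib2 are full sibs (a = 0.5); their offspring has F = 0.25,")
print("so its diagonal element is 1.25.")
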