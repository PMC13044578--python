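"""Classify proteins and a gene family as dark or light.

A protein is "light" if any of its database hits (at e <= 1e-5) carries an
informative description; it is "dark" if every hit is functionally
ambiguous ("hypothetical protein", ...) or it has no hits at all.  A
family is dark only when every member is dark.
"""

from darkog import AnnotationHit, Orthogroup, ProteinRef
from darkog.darkness import classify_orthogroup, classify_protein

p1 = ProteinRef("coral_A", "gene1")
p2 = ProteinRef("coral_B", "gene2")

hits_p1 = [
    AnnotationHit(p1, "nr001", 1e-30, 180.0, "hypothetical protein XP_1"),
    AnnotationHit(p1, "nr002", 1e-12, 90.0, "Uncharacterized Protein LOC5"),
]
hits_p2 = [
    AnnotationHit(p2, "nr003", 1e-25, 150.0, "hypothetical protein XP_2"),
    AnnotationHit(p2, "nr004", 1e-8, 75.0, "calmodulin-like protein"),
]

call1 = classify_protein(hits_p1)
call2 = classify_protein(hits_p2)
print(f"gene1: {call1.value}   (both hits ambiguous)")
print(f"gene2: {call2.value}  (one informative hit is enough)")

og = Orthogroup("OG000001", frozenset([p1, p2]))
og_call = classify_orthogroup(og, {p1: call1, p2: call2})
print(f"OG000001: {og_call.value}  (a family is dark only if ALL members are dark)")
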