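"""Place families at their lowest common ancestor and select conserved
dark families.

The LCA walk finds the most specific taxonomic rank at which every member
dataset carries the same taxon.  Dark families restricted to one of the
nested coral groups and covering at least half that group's datasets are
flagged as conserved.
"""

from darkog import DatasetRecord, Orthogroup, ProteinRef
from darkog.lineage import LineageGroupSpec, assign_lca, select_conserved_dark
from darkog.types import Darkness

records = {}
for i in range(4):
    suborder = "Complex" if i % 2 else "Robust"
    records[f"coral{i}"] = DatasetRecord(
        f"coral{i}", 100 + i,
        {"species": f"Coral species {i}", "suborder": suborder,
         "order": "Scleractinia", "class": "Hexacorallia",
         "phylum": "Cnidaria", "kingdom": "Metazoa"})
records["anemone"] = DatasetRecord(
    "anemone", 200, {"species": "Anemone sp", "order": "Actiniaria",
                     "class": "Hexacorallia", "phylum": "Cnidaria",
                     "kingdom": "Metazoa"})

coral_og = Orthogroup("OG_corals", frozenset(
    ProteinRef(d, "p1") for d in ("coral0", "coral1", "coral2")))
wide_og = Orthogroup("OG_wide", frozenset(
    ProteinRef(d, "p1") for d in ("coral0", "anemone")))

print("LCA placement (rank, taxon):")
print("  corals only ->", assign_lca(coral_og, records))
print("  coral + anemone ->", assign_lca(wide_og, records))

groups = LineageGroupSpec.from_dict({
    "Scleractinia": [f"coral{i}" for i in range(4)],
    "Hexacorallia": [f"coral{i}" for i in range(4)] + ["anemone"],
    "Cnidaria": [f"coral{i}" for i in range(4)] + ["anemone"],
})
coral_og.darkness = wide_og.darkness = Darkness.dark
selected = select_conserved_dark([coral_og, wide_og], groups, min_coverage=0.5)
for og in selected:
    print(f"conserved: {og.og_id} category={og.conserved_group} "
          f"coverage={og.annotations['coverage']:.2f}")
print("(OG_corals covers 3/4 = 75% of Scleractinia -> selected; OG_wide is a")
print(" 2/5 = 40% Hexacorallia family -> below the inclusive 50% bar)")
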