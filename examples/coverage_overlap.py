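"""Three-source annotation coverage of one proteome.

Partitions a proteome's sequences by which annotation resources cover
them (genome properties, a subsystems resource, a pathway resource):
the seven exclusive Venn regions plus the unannotated remainder.
"""

from genprops import overlap_partition

# protein identifier sets annotated by each resource (toy proteome of 20)
annotations = {
    "GP": {"p01", "p02", "p03", "p04", "p05", "p06", "p10"},
    "SS": {"p01", "p02", "p03", "p07", "p08", "p10", "p11"},
    "KEGG": {"p01", "p02", "p04", "p07", "p12"},
}

part = overlap_partition(annotations, total=20)
print(f"sources: {part.sources}")
print(f"annotated by all three : {part.all_three}")
for a, b in [("GP", "SS"), ("SS", "KEGG"), ("KEGG", "GP")]:
    print(f"{a} & {b} only        : {part.pair(a, b)}")
for s in part.sources:
    print(f"{s} only              : {part.only(s)}")
print(f"unannotated            : {part.unannotated}  (of {part.total})")
print(
    "\nThe eight counts are disjoint and sum to the proteome size; 'only'\n"
    "regions show each resource's unique contribution."
)
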