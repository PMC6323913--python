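"""Assign genome properties to a proteome from its InterPro matches.

Builds a miniature property set in code -- a two-step threonine-style
pathway, a biotin-style pathway and a metapath combining them -- then
evaluates it against a hand-written match table and prints the summary
and protein reports.
"""

from genprops import (
    Evidence,
    GenomeProperty,
    PropertyRegistry,
    PropertyType,
    Step,
    evaluate_all,
    parse_interproscan_tsv,
    protein_report,
    summary_report,
)

registry = PropertyRegistry([
    GenomeProperty(
        accession="GenProp0001",
        name="Threonine biosynthesis from aspartate semialdehyde",
        type=PropertyType.PATHWAY,
        threshold=0,
        steps=(
            Step(1, "homoserine_dh", evidences=(Evidence("IPR001342"),)),
            Step(2, "threonine_synthase", evidences=(Evidence("IPR004450"),)),
        ),
    ),
    GenomeProperty(
        accession="GenProp0002",
        name="Biotin biosynthesis",
        type=PropertyType.PATHWAY,
        threshold=0,
        steps=(
            Step(1, "bioF", evidences=(Evidence("IPR001917"),)),
            Step(2, "bioB", evidences=(Evidence("IPR002684"),)),
        ),
    ),
    GenomeProperty(
        accession="GenProp0010",
        name="Amino acid and cofactor biosynthesis",
        type=PropertyType.METAPATH,
        threshold=0,
        steps=(
            Step(1, "threonine", evidences=(Evidence("GenProp0001"),)),
            Step(2, "biotin", evidences=(Evidence("GenProp0002"),)),
        ),
    ),
])

# the simplified two-column dialect: protein<TAB>InterPro accession.
# Both threonine steps match; only one biotin step does.
matches = """\
YP_001\tIPR001342
YP_002\tIPR004450
YP_003\tIPR001917
"""

table = parse_interproscan_tsv(matches, label="example", simple=True)
results = evaluate_all(registry, table)

print(summary_report(results, registry))
print(protein_report(results, registry))
print(
    "The threonine pathway is YES (every required step matched), biotin is\n"
    "PARTIAL (1 of 2 required steps, above its threshold of 0), so the\n"
    "metapath combining them is PARTIAL as well: only a YES sub-property\n"
    "satisfies a metapath step."
)
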