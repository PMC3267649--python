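"""Cardinality restrictions: diols need at least two alcohol groups.

Derives alcohol, diol and triol classes from synthetic homologous series, adds
the curator's min-2 / min-3 carbinol restrictions, and shows that occurrence
counting separates ethanol, ethylene glycol and glycerol — while the triol
class self-organizes under diols.
"""

from chemontogen import (
    ClassSpec,
    RunConfig,
    SeriesSpec,
    classify_entity,
    entity_fingerprint,
    generate_series,
    parse_structure,
    run_pipeline,
)

specs = [
    ClassSpec(name="alcohols", members=generate_series(SeriesSpec(family="alcohols", count=7), seed=7)),
    ClassSpec(
        name="diols",
        members=generate_series(SeriesSpec(family="diols", count=7), seed=7),
        cardinality_overrides={"[#6][OX2H]": 2},
    ),
    ClassSpec(
        name="triols",
        members=generate_series(SeriesSpec(family="triols", count=7), seed=7),
        cardinality_overrides={"[#6][OX2H]": 3},
    ),
]
result = run_pipeline(RunConfig(seed=7), specs)

for smiles, name in [("CCO", "ethanol"), ("OCCO", "ethylene glycol"), ("OCC(O)CO", "glycerol")]:
    fp = entity_fingerprint(parse_structure(smiles, identifier=name), result.ontology.registry)
    satisfied, most_specific = classify_entity(fp, result.ontology, result.hierarchy)
    print(f"{name:16s} satisfies: {sorted(result.ontology.name_of(u) for u in satisfied)}")

print("inferred hierarchy edges (child -> parent):")
for child, parent in sorted(result.hierarchy.edge_names()):
    print("   ", " = ".join(child), "->", " = ".join(parent))
# Ethanol has one [#6][OX2H] occurrence (alcohol only), the glycol two (diol),
# glycerol three — so it satisfies the triol definition and, transitively, the
# diol and alcohol ones. Triols attach under diols purely by subsumption of
# their generated definitions.
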