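"""Mixing structure and molecular descriptors: 'Reactive Diols'.

Extends the diol definition with a molecular-weight <= 500 Dalton attribute
clause and shows that a 40-carbon diol is excluded while every fixture diol is
retained, with Reactive Diols =< Diols =< Alcohols in the inferred hierarchy.
"""

from chemontogen import (
    AttributeRestriction,
    ClassSpec,
    RunConfig,
    SeriesSpec,
    classify_entity,
    compute_molecular_weight,
    entity_fingerprint,
    generate_series,
    parse_structure,
    run_pipeline,
    to_manchester,
)

diols = generate_series(SeriesSpec(family="diols", count=7), seed=7)
specs = [
    ClassSpec(name="alcohols", members=generate_series(SeriesSpec(family="alcohols", count=7), seed=7)),
    ClassSpec(name="diols", members=diols, cardinality_overrides={"[#6][OX2H]": 2}),
    ClassSpec(
        name="reactive diols",
        members=diols,
        cardinality_overrides={"[#6][OX2H]": 2},
        attribute_restrictions=[AttributeRestriction("molecular weight", "le", hi=500.0)],
    ),
]
result = run_pipeline(RunConfig(seed=7), specs)
print(to_manchester(result.definitions["reactive diols"], result.ontology.registry))
print()

heavy = parse_structure("OC" + "C" * 38 + "CO", identifier="tetracontane-1,40-diol")
for mol in diols + [heavy]:
    fp = entity_fingerprint(mol, result.ontology.registry)
    satisfied, _ = classify_entity(fp, result.ontology, result.hierarchy)
    names = sorted(result.ontology.name_of(u) for u in satisfied)
    mw = compute_molecular_weight(mol)
    print(f"{mol.identifier:24s} MW={mw:6.1f}  -> {names}")
# Every fixture diol (MW well under 500) lands in 'reactive diols'; the heavy
# diol keeps its 'diols' membership but fails the attribute clause.
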