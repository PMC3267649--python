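"""Self-organization and ontology merging.

Derives four families (alcohols, diols, triols, amines) into formally defined
classes, infers the subsumption hierarchy, then shows that merging two
independently built ontologies reproduces the combined run exactly — shared
features unify automatically through their hash-derived URIs.
"""

from chemontogen import ClassSpec, RunConfig, SeriesSpec, generate_series, import_ontology, infer_hierarchy, run_pipeline

overrides = {"diols": {"[#6][OX2H]": 2}, "triols": {"[#6][OX2H]": 3}}
specs = [
    ClassSpec(
        name=fam,
        members=generate_series(SeriesSpec(family=fam, count=7), seed=7),
        cardinality_overrides=overrides.get(fam, {}),
    )
    for fam in ["alcohols", "diols", "triols", "amines"]
]

combined = run_pipeline(RunConfig(seed=7), specs)
print("combined-run hierarchy:")
for child, parent in sorted(combined.hierarchy.edge_names()):
    print("   ", " = ".join(child), "->", " = ".join(parent))

source_a = run_pipeline(RunConfig(seed=7), specs[:2])   # alcohols + diols
source_b = run_pipeline(RunConfig(seed=7), specs[2:])   # triols + amines
merged = import_ontology(source_a.ontology, source_b.ontology)
merged_hier = infer_hierarchy(merged)
print("merged two-source hierarchy equals combined run:",
      merged_hier.edge_names() == combined.hierarchy.edge_names())
shared = [u for p, u in merged.registry.items() if p.text == "[#6]"][0]
print("shared feature '[#6]' resolves to one URI:", shared.rsplit('/', 1)[-1][:12], "...")
# Because every feature URI is the SHA1 of its canonical pattern text, the two
# sources reference identical URIs for shared chemistry and the merge is a
# plain union — triols from source B still attach under diols from source A.
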