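"""Derive a consensus fingerprint for a small class of organic alcohols.

Builds the five-member training set by hand, mines every fragment and
abstraction level, screens the candidates at presence fraction 1.0, and prints
the consensus features and the principal characteristic substructures.
"""

from chemontogen import consensus_fingerprint, load_pattern_library, parse_structure, partition_class

train = [
    parse_structure(s, identifier=name)
    for s, name in [
        ("CO", "methanol"),
        ("CCO", "ethanol"),
        ("CCCO", "propan-1-ol"),
        ("CC(C)O", "propan-2-ol"),
        ("OCc1ccccc1", "benzyl alcohol"),
    ]
]

partition = partition_class(train, k=5)
fp = consensus_fingerprint(partition, library=load_pattern_library(), class_name="Organic Alcohols")

print("consensus features (present in every training member):")
for text in sorted(fp.feature_texts()):
    print("   ", text)
print("principal characteristic substructures (maximal under containment):")
for p in sorted(fp.principal, key=lambda p: p.text):
    print("   ", p.text)
# Every listed feature matches all five alcohols; [#6][OX2H] — a carbon bonded
# to a hydroxyl group — is the defining alcohol scaffold and shows up as
# principal because it contains, and is contained in no other, consensus feature.
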