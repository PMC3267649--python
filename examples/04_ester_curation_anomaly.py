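"""Detecting a curation error from failed convergence.

An N-linked pseudo-ester (RC(=O)ONR) injected into an ester training set
removes the ester consensus feature C(=O)OC while the carboxyl-like carbonyl
pattern survives; the convergence report names the offending member.
"""

from chemontogen import SeriesSpec, consensus_fingerprint, convergence_report, generate_series, load_pattern_library, partition_class
from chemontogen.workbench import _expected_pattern

library = load_pattern_library()
expected = _expected_pattern("C(=O)OC")

for label, corruption in [("clean", None), ("corrupted", "n_linked")]:
    members = generate_series(SeriesSpec(family="esters", count=4, corruption=corruption), seed=7)
    partition = partition_class(members, k=5)
    fp = consensus_fingerprint(partition, library=library, class_name="esters")
    report = convergence_report(fp, partition, expected)
    print(f"{label} training set ({len(partition.train)} members):")
    print("    expected ester pattern present:", report.expected_present)
    print("    carboxyl-like pattern retained:", "O=CO" in fp.feature_texts())
    print("    curation-error suspects:", report.non_matching_members or "none")
# The single member that fails to match the expected pattern is exactly the
# injected N-linked molecule — failed convergence doubles as curator QC.
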