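# Methods

## Model

The package operates on a single premise: chemical class specialization is
structure extension. A class is characterized by the set of structural
features present in **every** one of its members (its consensus fingerprint),
a subclass carries all of its parent's consensus features plus some of its
own, and a molecule belongs to a class exactly when it exhibits every feature
of the class's definition at the required multiplicity. Definitions are
therefore *necessary and sufficient* conjunctions — deterministic and
human-readable, unlike probabilistic QSAR-style classifiers — and a hierarchy
needs no curation: it follows from pairwise entailment between definitions.

Assumptions worth keeping in mind:

- **Consensus is exact.** A candidate feature is kept only at presence
  fraction 1.0 over the training set; a single mis-curated member deletes
  every feature it lacks. This is deliberate — failed convergence is the
  curation-error detector (see the ester regression in the tests and
  examples) — but it makes definitions sensitive to training-set coverage.
- **Monotone, negation-free logic.** Definitions say what must be present,
  never what must be absent. Structurally valid but chemically debatable
  edges follow (esters land under ethers; a carboxylic acid satisfies a
  purely structural alcohol definition when its features are a superset).
  Such edges are reported as-is, not suppressed.
- **Cardinality is curated, not mined.** Minimum occurrence counts (diols:
  `min 2` carbinol groups) are supplied as per-class overrides; the miner
  itself only establishes presence.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 5 | training-set size: the k least complex members (heavy atoms + bonds, ties by canonical SMILES) |
| `max_cuts` | 4 | maximum number of bonds deleted simultaneously during fragment enumeration |
| `min_heavy_atoms` | 1 | smallest fragment kept |
| `max_fragments` | 50 000 | per-molecule cap on bond subsets; exceeding it is an error, not a silent truncation |
| pattern library | ~60 entries | curated SMARTS (common functional groups, the general ester `C(=[O,S])OC`, ring-count primitives `[R1]`/`[R2]`); swappable via `--pattern-library` |
| `mode` | `strict` | subsumption by feature-URI identity; `implication` additionally lets a more specific pattern satisfy a more general restriction via graph containment |
| `cross_class_screening` | off | re-screen each class against all other classes' consensus patterns; off by default so a merged two-source run equals the merge of per-source runs |
| namespace | configurable IRI | base for class, property and feature URIs |

## Atom abstraction and pattern semantics

Seven abstraction modes annotate atoms for general type, aromaticity, ring
membership, full hydrogenation state, and the pairwise combinations of full
hydrogenation with the others. *Fully hydrogenated* means a terminal atom —
at most one heavy-atom neighbour, at least one hydrogen — and is encoded with
exact connectivity and hydrogen count (`[OX2H]`, `[CX4H3]`). Because
abstraction is computed on the parent molecule before fragmentation, a
mid-chain carbon exposed by a bond cut never masquerades as a methyl group.
Non-terminal atoms under a full-hydrogenation mode fall back to the base
mode's primitive; no negated primitives (e.g. "not aromatic" on a generic
atom) are ever generated.

Matching semantics are exact and intentionally simple:

- SMILES-level patterns constrain element, aromaticity and bond order
  exactly; hydrogen counts are ignored (substructure semantics).
- Abstracted SMARTS patterns constrain atoms by their primitives and treat
  every bond as *any bond*. The canonical display text writes bonds in the
  conventional adjacent style (`[#6][#8]`); the matcher compiles an explicit
  form (`[#6]~[#8]`) so that, e.g., `[#6][#6]` matches an alkene or an
  aromatic pair. All matching executes on RDKit's substructure engine via
  this generated query; an independent brute-force embedding enumerator
  validates the counts in the test suite.
- Distinct occurrences are distinct matched-atom *sets*: automorphic
  re-matchings collapse (benzene contains one six-ring, not twelve), while
  overlapping occurrences on different atom sets count separately. This is
  the count the cardinality clauses consume.

One consequence: fragments produced by opening an aromatic ring are kekulized
conjugated chains and do not match their aromatic parent at the SMILES level;
they drop out in fraction screening, and ring chemistry is carried by the
abstracted levels (`[#6;a]`, `[#6;R]`) and by intact-ring SMILES fragments.
A laxer "conjugated matches aromatic" tolerance was evaluated and rejected:
whether such a query bond matches depends on its context inside the query, so
subpatterns of a matching pattern could fail to match — breaking the soundness
of pattern containment, on which principal substructures rest.

## SMARTS canonicalization

Each atomic primitive maps to a synthetic isotope number; the assignment is
the primitive's rank in a fixed, sorted enumeration of all expressible
primitives (elements 1–118 × {generic, aromatic, ring} plus all terminal
X/H combinations), offset by 100. Rank in a *fixed* universe — rather than in
the set of primitives a run happens to produce — keeps canonicalization a pure
function: a pattern's canonical text never depends on what other patterns
exist. The isotope-tagged pseudo-molecule (all single bonds; the trick orders
atoms, not bonds) is canonicalized as an ordinary SMILES, and tokens are
translated back into primitives. Canonical texts are invariant under input
atom renumbering and idempotent; they are toolkit-specific, so cross-run
stability, not cross-toolkit identity, is the contract. A TSV sidecar of the
isotope table in use is written with run artifacts.

Feature URIs are `namespace + fg/ + SHA1(canonical text)` (40 lowercase hex
characters), which is what makes independently derived ontologies merge by
plain union.

## OWL encoding

Two documents: a flat functional-group ontology (classes with labels, no
hierarchy) imported by the class ontology. Feature restrictions use
`'has part' someValuesFrom` for minimum count 1 and a qualified minimum
cardinality otherwise; attribute clauses use `'has attribute' someValuesFrom`
an intersection of the attribute class, a `hasValue` datatype range
(`xsd:maxInclusive`/`minInclusive` facets — the printed `[= < 500]` is read as
≤ 500), and a `hasUnit` clause. Blank nodes are emitted from a sequential
factory so serialized output is byte-reproducible. The reader accepts exactly
this profile and raises with a list of offenders otherwise. Internal
subsumption (strict mode) reproduces on these axioms what an external DL
reasoner computes from the exported files, so external reasoners can still be
run on the output, but none is required or invoked.

Attribute entailment is interval containment over the same attribute *and*
unit; mixed units never entail (conservative, no unit conversion).

## The synthetic fixture generator

`generate_series` emulates small curated training sets as homologous series:
linear/branched alkyl skeletons plus family-defining groups, with diols and
triols carrying exactly two and three hydroxyls by construction. Each family
combines two fixed low-complexity *anchor* members with seed-sampled extras.
Anchors bound the consensus the way a curator's "complete coverage" does: the
alcohol anchors methanol and allyl alcohol keep an incidentally shared methyl
group out of the alcohol consensus, ethylene glycol and 1,3-propanediol do the
same for diols, and all triol templates share the anchors' 1,3-dioxy backbone
so held-out members still satisfy the derived definition. The ester corruption
directive appends the N-linked `CC(=O)ONC` to reproduce the curation-error
scenario.

What the generator does **not** emulate: charged or multi-component
structures, stereochemistry, tautomerism, large ring systems, or the breadth
and noise of real database classes. Passing tests therefore demonstrate the
machinery — mining, canonicalization, axiomatization, subsumption,
cardinality/attribute classification — on clean, aliphatic-dominated series;
they do not certify accuracy on real curated corpora, where training-set
coverage and curator acceptability judgments dominate. On the seven-family
held-out corpus the classifier scores ~93% correct with the remaining
inferences being structurally valid multi-class memberships (benzyl alcohol
also satisfying the benzene-derivative definition) that the source-class gold
standard does not list as acceptable.

## Numerical and procedural choices

- Complexity ties in partitioning break lexicographically by canonical
  SMILES; component ties in salt stripping break by molecular weight, then
  canonical SMILES.
- MCS is the connected maximum common subgraph with element-exact atoms and
  order-exact bonds (aromatic matches aromatic); the MCS-of-MCS closure runs
  a single second-order round, not a fixed-point iteration. MCS extractions
  that break aromatic sanitization are skipped with a log entry.
- Verbatim library patterns (OR/recursive SMARTS) are screened and used in
  definitions but excluded from principal-substructure maximality, where
  containment is undefined for them.
- Fraction screening uses exact equality with 1.0 — no tolerance.
- Randomness exists only in fixture generation; one seed in the run config
  reproduces every artifact byte-for-byte.

## Problem sizes

Default runs derive classes from 5-member training sets of molecules with
≤ 12 heavy atoms, fragment at ≤ 4 cuts, and classify a few dozen held-out
members; a full seven-family pipeline completes in seconds on one CPU. These
sizes are the package's chosen study conditions for its synthetic series; the
machinery itself is bounded only by the fragment cap and the combinatorics of
`max_cuts` on large ring systems.

## Known limitations

- No negation mining: classes defined by absence (ethers vs esters) cannot be
  separated automatically.
- No automatic cardinality detection; counts come from the curator.
- Exact-consensus mining is brittle to curation errors by design; the
  convergence report surfaces them but a human decides.
- SMILES-level matching ignores formal charges and stereochemistry.
- Higher-order graph features (fused-cage topology, nanotube-like classes)
  are out of reach of fragment-and-primitive mining; ring-count library
  primitives (`[R2]`) cover only part of that space.
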