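# chemontogen

Structure-based chemical class curation is still largely manual: a curator
studies known members of a class (say, ChEBI's diols), decides which
structural features define it, writes a textual definition and places the
class in a hierarchy by hand. `chemontogen` automates that loop. Given a small
curated set of member molecules, it derives a *formal, necessary-and-sufficient
class definition* from the substructures shared by every member, encodes it in
OWL, and lets such definitions **self-organize into a chemical ontology** that
can then classify arbitrary new molecules — including classes that need
cardinality clauses (diols: at least two alcohol groups) and numeric attribute
clauses (molecular weight ≤ 500 Da).

It is a library first (with a thin `chemontogen` command-line wrapper), aimed
at ontology curators and cheminformaticians who want transparent, logic-based
class definitions rather than black-box classifiers.

## The method

For a class with curated members, the pipeline:

1. **Partitions** the members, training on the *k* (default 5) least complex
   ones (heavy atoms + bonds) — the smallest members must already carry every
   pattern the class shares.
2. **Generates candidate features** per training member: all fragments
   obtainable by cutting up to 4 bonds, at the native SMILES level and at
   seven atom-abstraction levels (generic `[#6]`, aromatic `[#6;a]`, ring
   `[#6;R]`, and terminal-hydrogenation forms such as `[OX2H]` and `[CX4H3]`,
   plus their combinations); plus a predefined SMARTS library; plus pairwise
   maximum common substructures of the smallest members and one MCS-of-MCS
   round.
3. **Canonicalizes** every pattern. SMARTS patterns have no standard canonical
   form, so each atomic primitive is mapped to a unique synthetic isotope, the
   pseudo-molecule is ordered by ordinary canonical-SMILES ranking (atomic
   mass participates in the ranking), and the isotope tokens are translated
   back through a lookup table.
4. **Screens** each candidate over the training set and keeps exactly those
   with presence fraction 1.0 — the *consensus fingerprint*. Features that
   contain, but are not contained in, other features (by subgraph-embedding
   subsumption) are the *principal characteristic substructures*, the class's
   defining scaffolds.
5. **Axiomatizes**: every feature gets a URI from the SHA1 hash of its
   canonical text in a flat functional-group registry; the class becomes an
   equivalent-class conjunction `'molecular entity' and 'has part' some F1 and
   …`, with curator-supplied minimum cardinalities (`'has part' min 2
   '[#6][OX2H]'`) and attribute clauses (`'has attribute' some ('molecular
   weight' and 'has value' [= < 500] and 'has unit' some 'Dalton')`). OWL 2
   RDF/XML in, OWL 2 RDF/XML out.
6. **Reasons**: class A is subsumed by B when every restriction of B appears
   in A at least as strongly (same feature URI, min-count ≥, attribute
   interval ⊆). Hash URIs make this equivalent to what a DL reasoner infers
   from the exported OWL. Equivalent classes merge; the transitive reduction
   is the hierarchy.
7. **Classifies**: a molecule is fingerprinted by counting *distinct
   occurrences* (distinct matched-atom sets) of every registry feature;
   it belongs to every class whose restrictions its counts and attributes
   satisfy.

Because nothing external is needed, a fixture generator produces homologous
series (alcohols, diols, triols, amines, esters, ethers, carboxylic acids,
benzenes) with a known nested hierarchy for tests and demonstrations.

## Worked example

```bash
python examples/01_derive_alcohols.py
```

prints

```
consensus features (present in every training member):
    C
    CO
    O
    [#6]
    [#6][#8]
    [#6][OX2H]
    [#8]
    [OX2H]
    [OX2H][CX4]
principal characteristic substructures (maximal under containment):
    CO
    [#6][OX2H]
```

Reading the numbers: from five small alcohols (methanol, ethanol, the two
propanols, benzyl alcohol) the miner recovers carbon `[#6]`, oxygen `[#8]`,
the carbon–oxygen bond `[#6][#8]` and the carbinol group `[#6][OX2H]` as
consensus, along with their SMILES-level counterparts and the library's
aliphatic-alcohol pattern. The two principal substructures are the maximal
ones: the exact fragment `CO` (an aliphatic carbon bonded to oxygen) and
`[#6][OX2H]` (any carbon — aromatic included — bearing a hydroxyl), which
between them contain every other consensus feature. `EquivalentTo` conjunction
of these features *is* the generated alcohol class definition.

The other examples show cardinality (`02`), attribute clauses (`03`), curation
error detection through failed convergence (`04`), hierarchy self-organization
and two-source ontology merging (`05`), and held-out classification scoring
(`06`).

## Command line

```bash
chemontogen fixtures --family diols --count 7 --seed 1 --out diols.smi
chemontogen derive --name diols --train diols.smi --expect "[#6][OX2H]"
chemontogen run --config run.yaml --out results/
chemontogen reason --ontology results/classes.owl
chemontogen classify --ontology results/classes.owl --input new_molecules.smi
chemontogen merge a.owl b.owl --out merged.owl
```

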