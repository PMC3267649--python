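"""Entity fingerprinting, class-membership decisions and accuracy scoring.

A molecule is screened against every feature in the functional-group registry;
each feature's *distinct occurrences* are counted as distinct sets of matched
atoms (embeddings differing only by a pattern automorphism collapse to one
occurrence, so benzene contains one six-ring, not twelve).  Class membership
then reduces to comparing occurrence counts against the min-cardinality
restrictions of each class definition and checking attribute clauses such as a
molecular-weight bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional

from rdkit import Chem

from .canonical import CanonicalPattern
from .molgraph import Molecule, compute_molecular_weight

if TYPE_CHECKING:  # pragma: no cover
    from .axioms import FunctionalGroupRegistry, Ontology
    from .reasoner import Hierarchy

logger = logging.getLogger(__name__)

_QUERY_CACHE: dict[tuple[str, str], Optional[Chem.Mol]] = {}


def _compile(pattern: CanonicalPattern) -> Optional[Chem.Mol]:
    """Executable RDKit query for a pattern.

    Graph-backed patterns (canonical SMILES fragments and abstracted SMARTS)
    compile through the explicit query writer so their semantics are exactly
    the pattern graph's: exact atoms and bond orders at the SMILES level,
    primitive constraints with any-bond edges at the SMARTS level.  Verbatim
    library entries compile as plain SMARTS.
    """
    key = (pattern.kind, pattern.text)
    if key not in _QUERY_CACHE:
        if pattern.graph is not None:
            from .canonical import query_smarts

            q = Chem.MolFromSmarts(query_smarts(pattern.graph))
        else:
            q = Chem.MolFromSmarts(pattern.text)
        if q is None:
            logger.warning("pattern %r (%s) failed to compile; excluded", pattern.text, pattern.kind)
        _QUERY_CACHE[key] = q
    return _QUERY_CACHE[key]


def count_distinct_matches(mol: Molecule, feature: CanonicalPattern) -> int:
    """Number of distinct atom-index sets over which the feature embeds."""
    q = _compile(feature)
    if q is None:
        return 0
    matches = mol.rdmol.GetSubstructMatches(q, uniquify=True)
    return len({frozenset(m) for m in matches})


def has_match(mol: Molecule, feature: CanonicalPattern) -> bool:
    q = _compile(feature)
    if q is None:
        return False
    return mol.rdmol.HasSubstructMatch(q)


@dataclass
class EntityFingerprint:
    """Per-molecule feature occurrence counts plus attribute values."""

    entity_id: str
    counts: dict[str, int]  # feature URI -> distinct occurrence count
    attributes: dict[str, tuple[float, str]]  # attribute name -> (value, unit)
    skipped_features: list[str] = field(default_factory=list)


def entity_fingerprint(mol: Molecule, registry: "FunctionalGroupRegistry") -> EntityFingerprint:
    """Screen one molecule against every registry feature.

    Zero counts are recorded explicitly; features whose pattern fails to
    compile are excluded and reported in ``skipped_features``.  The molecular
    weight attribute is always attached.
    """
    if len(registry) == 0:
        raise ValueError("empty functional-group registry")
    counts: dict[str, int] = {}
    skipped: list[str] = []
    for pattern, uri in registry.items():
        if _compile(pattern) is None:
            skipped.append(uri)
            continue
        counts[uri] = count_distinct_matches(mol, pattern)
    return EntityFingerprint(
        entity_id=mol.identifier or mol.source_smiles,
        counts=counts,
        attributes={"molecular weight": (compute_molecular_weight(mol), "dalton")},
        skipped_features=skipped,
    )


def _satisfies(fp: EntityFingerprint, cd) -> bool:
    for uri, restriction in cd.restrictions.items():
        if fp.counts.get(uri, 0) < restriction.min_count:
            return False
    for attr in cd.attributes:
        got = fp.attributes.get(attr.attribute)
        if got is None:
            return False
        value, unit = got
        if unit != attr.unit or not attr.accepts(value):
            return False
    return True


def classify_entity(
    fp: EntityFingerprint,
    ont: "Ontology",
    hier: Optional["Hierarchy"] = None,
) -> tuple[set[str], set[str]]:
    """All satisfied class URIs and the most-specific subset.

    ``all_satisfied`` is closed under hierarchy ancestors by construction of
    the subsumption rule; ``most_specific`` drops every class that is a strict
    ancestor of another satisfied class.
    """
    from .reasoner import infer_hierarchy

    satisfied = {uri for uri, cd in ont.classes.items() if _satisfies(fp, cd)}
    if hier is None:
        hier = infer_hierarchy(ont)
    ancestors_of_satisfied: set[str] = set()
    for uri in satisfied:
        ancestors_of_satisfied |= hier.strict_ancestors(uri)
    most_specific = satisfied - ancestors_of_satisfied
    return satisfied, most_specific


@dataclass
class ClassificationReport:
    """Per-entity inferred classes plus run-level totals."""

    entries: list[dict] = field(default_factory=list)  # entity_id, all, most_specific

    def add(self, entity_id: str, all_satisfied: set[str], most_specific: set[str]) -> None:
        self.entries.append(
            {
                "entity_id": entity_id,
                "all_satisfied": sorted(all_satisfied),
                "most_specific": sorted(most_specific),
            }
        )

    @property
    def total_inferences(self) -> int:
        return sum(len(e["most_specific"]) for e in self.entries)


def evaluate(
    report: ClassificationReport,
    gold: Mapping[str, tuple[str, Optional[set[str]]]],
    hier: Optional["Hierarchy"] = None,
    name_of: Optional[Mapping[str, str]] = None,
) -> dict:
    """Score most-specific inferences against gold annotations.

    ``gold`` maps entity_id -> (assigned class name, acceptable class names or
    None).  When the acceptable set is None it defaults to the assigned class
    plus its hierarchy descendants (an entity assigned "alcohols" but inferred
    as a diol scores correct, not direct).  Entities missing from gold are
    flagged and excluded from the totals.
    """
    name_of = name_of or {}
    per_category: dict[str, dict[str, int]] = {}
    flagged: list[str] = []
    for entry in report.entries:
        eid = entry["entity_id"]
        if eid not in gold:
            flagged.append(eid)
            continue
        assigned, acceptable = gold[eid]
        if acceptable is None:
            acceptable = {assigned}
            if hier is not None:
                acceptable |= hier.descendant_names(assigned)
        cat = per_category.setdefault(assigned, {"inferences": 0, "direct": 0, "correct": 0})
        for uri in entry["most_specific"]:
            inferred = name_of.get(uri, uri)
            cat["inferences"] += 1
            if inferred == assigned:
                cat["direct"] += 1
            if inferred in acceptable:
                cat["correct"] += 1

    def pct(part: int, whole: int) -> float:
        return round(100.0 * part / whole, 1) if whole else 0.0

    rows = []
    totals = {"inferences": 0, "direct": 0, "correct": 0}
    for cat in sorted(per_category):
        c = per_category[cat]
        rows.append(
            {
                "category": cat,
                "inferences": c["inferences"],
                "direct": c["direct"],
                "direct_pct": pct(c["direct"], c["inferences"]),
                "correct": c["correct"],
                "correct_pct": pct(c["correct"], c["inferences"]),
            }
        )
        for k in totals:
            totals[k] += c[k]
    return {
        "categories": rows,
        "total_inferences": totals["inferences"],
        "direct": totals["direct"],
        "direct_pct": pct(totals["direct"], totals["inferences"]),
        "correct": totals["correct"],
        "correct_pct": pct(totals["correct"], totals["inferences"]),
        "flagged_entities": flagged,
    }


def summary_table(summary: dict) -> str:
    """Render an evaluation summary as a TSV table (category rows + total)."""
    lines = ["Tested Category\tTotal Inferences\tDirect Inferences\tCorrect Inferences"]
    for row in summary["categories"]:
        lines.append(
            f"{row['category']}\t{row['inferences']}\t"
            f"{row['direct']} ({row['direct_pct']})\t{row['correct']} ({row['correct_pct']})"
        )
    lines.append(
        f"Total\t{summary['total_inferences']}\t"
        f"{summary['direct']} ({summary['direct_pct']})\t{summary['correct']} ({summary['correct_pct']})"
    )
    return "\n".join(lines)


def export_instance_rdf(fp: EntityFingerprint, registry: "FunctionalGroupRegistry", namespace: Optional[str] = None):
    """RDF document with one individual per entity and one explicitly distinct
    individual per feature occurrence, linked mereologically to the entity."""
    from rdflib import RDF, BNode, Graph, Literal, URIRef
    from rdflib.namespace import OWL, RDFS, XSD

    ns = namespace or registry.namespace
    g = Graph()
    ent = URIRef(f"{ns}entity/{fp.entity_id}")
    has_part = URIRef(f"{ns}property/hasPart")
    has_attr = URIRef(f"{ns}property/hasAttribute")
    has_value = URIRef(f"{ns}property/hasValue")
    has_unit = URIRef(f"{ns}property/hasUnit")
    g.add((ent, RDF.type, OWL.NamedIndividual))
    occurrences = []
    for pattern, uri in registry.items():
        n = fp.counts.get(uri, 0)
        for k in range(n):
            occ = URIRef(f"{ns}entity/{fp.entity_id}/occurrence/{uri.rsplit('/', 1)[-1]}/{k}")
            g.add((occ, RDF.type, URIRef(uri)))
            g.add((ent, has_part, occ))
            occurrences.append(occ)
    if occurrences:
        alldiff = BNode()
        g.add((alldiff, RDF.type, OWL.AllDifferent))
        from rdflib.collection import Collection

        members = BNode()
        Collection(g, members, occurrences)
        g.add((alldiff, OWL.distinctMembers, members))
    for attr_name, (value, unit) in fp.attributes.items():
        attr = BNode()
        g.add((ent, has_attr, attr))
        g.add((attr, RDFS.label, Literal(attr_name)))
        g.add((attr, has_value, Literal(float(value), datatype=XSD.double)))
        g.add((attr, has_unit, Literal(unit)))
    return g


def counts_from_instance_rdf(graph, registry: "FunctionalGroupRegistry") -> dict[str, int]:
    """Recover per-feature occurrence counts from an exported RDF document."""
    from rdflib import RDF, URIRef

    counts = {uri: 0 for _, uri in registry.items()}
    for _s, _p, o in graph.triples((None, RDF.type, None)):
        if str(o) in counts:
            counts[str(o)] += 1
    return counts
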