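"""Formal class definitions, the flat functional-group registry, and OWL I/O.

Every canonical pattern gets a stable URI formed from the 40-character
lowercase hex SHA1 of its canonical text, so independently generated
ontologies that share a feature automatically share its URI.  The registry is
deliberately flat: it declares functional groups and their labels, nothing
else.  A class definition is an equivalent-class (necessary and sufficient)
conjunction over the root primitive 'molecular entity': one 'has part'
restriction per consensus feature (someValuesFrom for min 1, a qualified
min-cardinality otherwise) plus optional 'has attribute' clauses carrying a
numeric range and a unit (e.g. molecular weight =< 500 Dalton).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from rdflib import BNode, Graph, Literal, RDF, RDFS, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, XSD

from .canonical import CanonicalPattern, smiles_pattern, verbatim_pattern
from .errors import MergeConflictError, UnsupportedAxiomError

DEFAULT_NAMESPACE = "http://example.org/chemontogen/"
ROOT_CLASS_NAME = "molecular entity"


def functional_group_uri(pattern: CanonicalPattern | str, namespace: str = DEFAULT_NAMESPACE) -> str:
    """namespace + 40 lowercase hex chars of SHA1(canonical pattern text)."""
    text = pattern.text if isinstance(pattern, CanonicalPattern) else pattern
    digest = hashlib.sha1(text.encode("utf-8")).hexdigest()
    return f"{namespace}fg/{digest}"


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "-", name.strip()).strip("-").lower()


def class_uri(name: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return f"{namespace}class/{_slug(name)}"


class FunctionalGroupRegistry:
    """Flat catalog: canonical pattern text -> (pattern, URI)."""

    def __init__(self, namespace: str = DEFAULT_NAMESPACE):
        self.namespace = namespace
        self._entries: dict[str, tuple[CanonicalPattern, str]] = {}

    def register(self, pattern: CanonicalPattern) -> str:
        entry = self._entries.get(pattern.text)
        if entry is None:
            uri = functional_group_uri(pattern, self.namespace)
            self._entries[pattern.text] = (pattern, uri)
            return uri
        return entry[1]

    def uri_for(self, text: str) -> Optional[str]:
        entry = self._entries.get(text)
        return entry[1] if entry else None

    def label_for(self, uri: str) -> Optional[str]:
        for text, (_p, u) in self._entries.items():
            if u == uri:
                return text
        return None

    def pattern_for(self, uri: str) -> Optional[CanonicalPattern]:
        for _text, (p, u) in self._entries.items():
            if u == uri:
                return p
        return None

    def items(self) -> Iterable[tuple[CanonicalPattern, str]]:
        for text in sorted(self._entries):
            yield self._entries[text]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, text: str) -> bool:
        return text in self._entries

    def write_tsv(self, path: str | Path) -> None:
        lines = ["uri\tlabel\tkind"]
        for pattern, uri in self.items():
            lines.append(f"{uri}\t{pattern.text}\t{pattern.kind}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class FeatureRestriction:
    feature_uri: str
    min_count: int = 1
    label: str = ""

    def __post_init__(self):
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True)
class AttributeRestriction:
    """A numeric attribute clause, e.g. molecular weight =< 500 Dalton."""

    attribute: str
    comparator: str  # 'le', 'ge' or 'interval'
    lo: Optional[float] = None
    hi: Optional[float] = None
    unit: str = "dalton"

    def __post_init__(self):
        if self.comparator not in {"le", "ge", "interval"}:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.comparator == "le" and self.hi is None:
            raise ValueError("'le' needs hi")
        if self.comparator == "ge" and self.lo is None:
            raise ValueError("'ge' needs lo")
        if self.comparator == "interval":
            if self.lo is None or self.hi is None:
                raise ValueError("'interval' needs lo and hi")
            if self.lo > self.hi:
                raise ValueError("interval lower bound exceeds upper bound")

    @property
    def interval(self) -> tuple[float, float]:
        return (
            self.lo if self.lo is not None else float("-inf"),
            self.hi if self.hi is not None else float("inf"),
        )

    def accepts(self, value: float) -> bool:
        lo, hi = self.interval
        return lo <= value <= hi

    def entailed_by(self, other: "AttributeRestriction") -> bool:
        """True iff ``other`` is at least as strong: same attribute and unit,
        and other's allowed interval is contained in this one's."""
        if self.attribute != other.attribute or self.unit != other.unit:
            return False
        lo, hi = self.interval
        olo, ohi = other.interval
        return lo <= olo and ohi <= hi


@dataclass
class ClassDefinition:
    """Equivalent-class conjunction of feature and attribute restrictions."""

    name: str
    uri: str
    restrictions: dict[str, FeatureRestriction] = field(default_factory=dict)
    attributes: tuple[AttributeRestriction, ...] = ()
    parent_primitive: str = ROOT_CLASS_NAME
    provenance: str = ""

    def structurally_equal(self, other: "ClassDefinition") -> bool:
        return (
            self.uri == other.uri
            and self.restrictions == other.restrictions
            and set(self.attributes) == set(other.attributes)
            and self.parent_primitive == other.parent_primitive
        )


def build_class_definition(
    name: str,
    fp,
    registry: FunctionalGroupRegistry,
    cardinality_overrides: Optional[Mapping[str, int]] = None,
    attribute_restrictions: Iterable[AttributeRestriction] = (),
    namespace: Optional[str] = None,
) -> ClassDefinition:
    """One FeatureRestriction per consensus feature; min counts come from the
    curator overrides (cardinality is not screened for automatically).

    Overrides must reference patterns actually present in the fingerprint.
    """
    overrides = dict(cardinality_overrides or {})
    attributes = tuple(attribute_restrictions)
    features = sorted(fp.features, key=lambda p: p.text) if fp is not None else []
    if not features and not attributes:
        raise ValueError(f"class {name!r}: empty fingerprint and no attribute restrictions")
    texts = {p.text for p in features}
    unknown = set(overrides) - texts
    if unknown:
        raise ValueError(
            f"class {name!r}: cardinality overrides for patterns not in the fingerprint: {sorted(unknown)}"
        )
    ns = namespace or registry.namespace
    restrictions: dict[str, FeatureRestriction] = {}
    for pattern in features:
        uri = registry.register(pattern)
        restrictions[uri] = FeatureRestriction(
            feature_uri=uri,
            min_count=overrides.get(pattern.text, 1),
            label=pattern.text,
        )
    return ClassDefinition(
        name=name,
        uri=class_uri(name, ns),
        restrictions=restrictions,
        attributes=attributes,
        provenance=getattr(fp, "class_name", "") or name,
    )


@dataclass
class Ontology:
    """Functional-group registry + class definitions (+ source imports)."""

    registry: FunctionalGroupRegistry
    classes: dict[str, ClassDefinition] = field(default_factory=dict)
    imports: list[str] = field(default_factory=list)

    @property
    def namespace(self) -> str:
        return self.registry.namespace

    def add_class(self, cd: ClassDefinition) -> None:
        existing = self.classes.get(cd.uri)
        if existing is not None and not existing.structurally_equal(cd):
            raise MergeConflictError(f"conflicting definitions for class {cd.name!r} ({cd.uri})")
        self.classes[cd.uri] = cd

    def name_of(self, uri: str) -> str:
        cd = self.classes.get(uri)
        return cd.name if cd else uri

    def structurally_equal(self, other: "Ontology") -> bool:
        if set(self.classes) != set(other.classes):
            return False
        if any(not self.classes[u].structurally_equal(other.classes[u]) for u in self.classes):
            return False
        mine = {t: u for t, (_p, u) in self.registry._entries.items()}
        theirs = {t: u for t, (_p, u) in other.registry._entries.items()}
        return mine == theirs


def import_ontology(a: Ontology, b: Ontology) -> Ontology:
    """Union of registries and classes; URI identity merges shared features.

    Same class URI with structurally different definitions is a merge
    conflict; identical URIs deduplicate silently.
    """
    merged = Ontology(registry=FunctionalGroupRegistry(a.namespace), imports=sorted(set(a.imports) | set(b.imports)))
    for src in (a, b):
        for text, (pattern, uri) in src.registry._entries.items():
            existing = merged.registry.uri_for(text)
            if existing is not None and existing != uri:
                raise MergeConflictError(f"feature {text!r} has conflicting URIs {existing} / {uri}")
            merged.registry._entries.setdefault(text, (pattern, uri))
    for src in (a, b):
        for cd in src.classes.values():
            merged.add_class(cd)
    return merged


# --- Manchester-style rendering -------------------------------------------

_CMP_TEXT = {"le": "[= < {hi}]", "ge": "[> = {lo}]", "interval": "[{lo} .. {hi}]"}


def to_manchester(cd: ClassDefinition, registry: FunctionalGroupRegistry) -> str:
    """Human-readable equivalent-class text in the printed report style."""
    lines = [f"'{cd.name}'", "EquivalentTo", f"'{cd.parent_primitive.capitalize()}'"]
    restrictions = sorted(cd.restrictions.values(), key=lambda r: (r.label or r.feature_uri))
    for r in restrictions:
        label = r.label or registry.label_for(r.feature_uri) or r.feature_uri
        if r.min_count == 1:
            lines.append(f"and 'has part' some '{label}'")
        else:
            lines.append(f"and 'has part' min {r.min_count} '{label}'")
    for attr in sorted(cd.attributes, key=lambda x: (x.attribute, x.interval)):
        rng = _CMP_TEXT[attr.comparator].format(lo=attr.lo, hi=attr.hi)
        lines.append(
            f"and 'has attribute' some ('{attr.attribute}' and 'has value' {rng} "
            f"and 'has unit' some '{attr.unit.capitalize()}')"
        )
    return "\n".join(lines)


# --- OWL 2 RDF/XML serialization -------------------------------------------


def _vocab(namespace: str) -> dict[str, URIRef]:
    ns = namespace
    return {
        "hasPart": URIRef(f"{ns}property/hasPart"),
        "hasAttribute": URIRef(f"{ns}property/hasAttribute"),
        "hasValue": URIRef(f"{ns}property/hasValue"),
        "hasUnit": URIRef(f"{ns}property/hasUnit"),
        "root": URIRef(class_uri(ROOT_CLASS_NAME, ns)),
        "attrBase": URIRef(f"{ns}attribute/"),
        "unitBase": URIRef(f"{ns}unit/"),
    }


def _fg_path(path: Path) -> Path:
    return path.with_name(path.stem + ".functional_groups" + path.suffix)


def _rdf_list(g: Graph, items: list, bnode: "_NodeFactory"):
    """RDF collection with factory-labelled cons cells (reproducible output)."""
    if not items:
        return RDF.nil
    head = bnode()
    cur = head
    for k, item in enumerate(items):
        g.add((cur, RDF.first, item))
        if k == len(items) - 1:
            g.add((cur, RDF.rest, RDF.nil))
        else:
            nxt = bnode()
            g.add((cur, RDF.rest, nxt))
            cur = nxt
    return head


class _NodeFactory:
    """Sequential blank-node labels so serialized output is reproducible."""

    def __init__(self) -> None:
        self.n = 0

    def __call__(self) -> BNode:
        self.n += 1
        return BNode(f"b{self.n:06d}")


def write_owl(ont: Ontology, path: str | Path) -> tuple[Path, Path]:
    """Write the class ontology and its imported functional-group document.

    Returns (classes path, functional-group path).  A registry TSV sidecar is
    written next to them.
    """
    path = Path(path)
    fg_path = _fg_path(path)
    v = _vocab(ont.namespace)

    fg = Graph()
    fg_iri = URIRef(f"{ont.namespace}ontology/functional-groups")
    fg.add((fg_iri, RDF.type, OWL.Ontology))
    for pattern, uri in ont.registry.items():
        node = URIRef(uri)
        fg.add((node, RDF.type, OWL.Class))
        fg.add((node, RDFS.label, Literal(pattern.text)))
        fg.add((node, RDFS.comment, Literal(f"kind={pattern.kind}")))
    fg.serialize(destination=str(fg_path), format="xml")

    g = Graph()
    bnode = _NodeFactory()
    ont_iri = URIRef(f"{ont.namespace}ontology/classes")
    g.add((ont_iri, RDF.type, OWL.Ontology))
    g.add((ont_iri, OWL.imports, fg_iri))
    for imp in ont.imports:
        g.add((ont_iri, OWL.imports, URIRef(imp)))
    g.add((v["root"], RDF.type, OWL.Class))
    g.add((v["root"], RDFS.label, Literal(ROOT_CLASS_NAME)))
    g.add((v["hasPart"], RDF.type, OWL.ObjectProperty))
    g.add((v["hasAttribute"], RDF.type, OWL.ObjectProperty))
    g.add((v["hasValue"], RDF.type, OWL.DatatypeProperty))
    g.add((v["hasUnit"], RDF.type, OWL.ObjectProperty))

    for uri in sorted(ont.classes):
        cd = ont.classes[uri]
        cls = URIRef(uri)
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.label, Literal(cd.name)))
        members: list = [v["root"]]
        for r in sorted(cd.restrictions.values(), key=lambda r: r.feature_uri):
            rest = bnode()
            g.add((rest, RDF.type, OWL.Restriction))
            g.add((rest, OWL.onProperty, v["hasPart"]))
            if r.min_count == 1:
                g.add((rest, OWL.someValuesFrom, URIRef(r.feature_uri)))
            else:
                g.add((rest, OWL.minQualifiedCardinality, Literal(r.min_count, datatype=XSD.nonNegativeInteger)))
                g.add((rest, OWL.onClass, URIRef(r.feature_uri)))
            members.append(rest)
        for attr in sorted(cd.attributes, key=lambda x: (x.attribute, x.interval)):
            members.append(_attribute_node(g, attr, v, bnode))
        inter = bnode()
        g.add((inter, RDF.type, OWL.Class))
        g.add((inter, OWL.intersectionOf, _rdf_list(g, members, bnode)))
        g.add((cls, OWL.equivalentClass, inter))
    g.serialize(destination=str(path), format="xml")

    ont.registry.write_tsv(path.with_suffix(".registry.tsv"))
    return path, fg_path


def _attribute_node(g: Graph, attr: AttributeRestriction, v: dict, bnode: _NodeFactory) -> BNode:
    rest = bnode()
    g.add((rest, RDF.type, OWL.Restriction))
    g.add((rest, OWL.onProperty, v["hasAttribute"]))

    attr_class = URIRef(str(v["attrBase"]) + _slug(attr.attribute))
    g.add((attr_class, RDF.type, OWL.Class))
    g.add((attr_class, RDFS.label, Literal(attr.attribute)))
    unit_class = URIRef(str(v["unitBase"]) + _slug(attr.unit))
    g.add((unit_class, RDF.type, OWL.Class))
    g.add((unit_class, RDFS.label, Literal(attr.unit)))

    facets = []
    if attr.lo is not None:
        b = bnode()
        g.add((b, XSD.minInclusive, Literal(float(attr.lo), datatype=XSD.double)))
        facets.append(b)
    if attr.hi is not None:
        b = bnode()
        g.add((b, XSD.maxInclusive, Literal(float(attr.hi), datatype=XSD.double)))
        facets.append(b)
    datarange = bnode()
    g.add((datarange, RDF.type, RDFS.Datatype))
    g.add((datarange, OWL.onDatatype, XSD.double))
    g.add((datarange, OWL.withRestrictions, _rdf_list(g, facets, bnode)))

    value_rest = bnode()
    g.add((value_rest, RDF.type, OWL.Restriction))
    g.add((value_rest, OWL.onProperty, v["hasValue"]))
    g.add((value_rest, OWL.someValuesFrom, datarange))

    unit_rest = bnode()
    g.add((unit_rest, RDF.type, OWL.Restriction))
    g.add((unit_rest, OWL.onProperty, v["hasUnit"]))
    g.add((unit_rest, OWL.someValuesFrom, unit_class))

    inner = bnode()
    g.add((inner, RDF.type, OWL.Class))
    g.add((inner, OWL.intersectionOf, _rdf_list(g, [attr_class, value_rest, unit_rest], bnode)))
    g.add((rest, OWL.someValuesFrom, inner))
    return rest


def read_owl(path: str | Path, namespace: str = DEFAULT_NAMESPACE) -> Ontology:
    """Read an ontology previously produced by :func:`write_owl`.

    The round trip is lossless for the supported profile; restriction shapes
    outside it raise :class:`UnsupportedAxiomError` listing the offenders.
    """
    path = Path(path)
    g = Graph()
    g.parse(str(path), format="xml")
    fg_path = _fg_path(path)
    fg = Graph()
    if fg_path.exists():
        fg.parse(str(fg_path), format="xml")

    v = _vocab(namespace)
    registry = FunctionalGroupRegistry(namespace)
    kind_by_uri: dict[str, str] = {}
    for node in fg.subjects(RDF.type, OWL.Class):
        label = fg.value(node, RDFS.label)
        if label is None:
            continue
        comment = str(fg.value(node, RDFS.comment) or "kind=verbatim")
        kind = comment.split("=", 1)[1] if "=" in comment else "verbatim"
        pattern = _pattern_from_label(str(label), kind)
        registry._entries[pattern.text] = (pattern, str(node))
        kind_by_uri[str(node)] = kind

    ont = Ontology(registry=registry)
    offenders: list[str] = []
    for cls in g.subjects(OWL.equivalentClass, None):
        label = str(g.value(cls, RDFS.label) or cls)
        inter = g.value(cls, OWL.equivalentClass)
        lst = g.value(inter, OWL.intersectionOf)
        if lst is None:
            offenders.append(f"{label}: equivalentClass without intersectionOf")
            continue
        restrictions: dict[str, FeatureRestriction] = {}
        attributes: list[AttributeRestriction] = []
        for member in Collection(g, lst):
            if member == v["root"]:
                continue
            if (member, RDF.type, OWL.Restriction) not in g:
                offenders.append(f"{label}: non-restriction conjunct {member}")
                continue
            prop = g.value(member, OWL.onProperty)
            if prop == v["hasPart"]:
                some = g.value(member, OWL.someValuesFrom)
                if some is not None:
                    uri = str(some)
                    restrictions[uri] = FeatureRestriction(uri, 1, registry.label_for(uri) or "")
                    continue
                n = g.value(member, OWL.minQualifiedCardinality)
                onc = g.value(member, OWL.onClass)
                if n is not None and onc is not None:
                    uri = str(onc)
                    restrictions[uri] = FeatureRestriction(uri, int(n), registry.label_for(uri) or "")
                    continue
                offenders.append(f"{label}: unsupported hasPart restriction shape")
            elif prop == v["hasAttribute"]:
                attr = _read_attribute(g, member, v, offenders, label)
                if attr is not None:
                    attributes.append(attr)
            else:
                offenders.append(f"{label}: unknown property {prop}")
        ont.classes[str(cls)] = ClassDefinition(
            name=label,
            uri=str(cls),
            restrictions=restrictions,
            attributes=tuple(attributes),
        )
    if offenders:
        raise UnsupportedAxiomError(offenders)
    return ont


def _read_attribute(g: Graph, rest, v, offenders: list, label: str) -> Optional[AttributeRestriction]:
    inner = g.value(rest, OWL.someValuesFrom)
    lst = g.value(inner, OWL.intersectionOf)
    if lst is None:
        offenders.append(f"{label}: attribute restriction without intersection")
        return None
    attr_name = unit = None
    lo = hi = None
    for member in Collection(g, lst):
        if (member, RDF.type, OWL.Restriction) in g:
            prop = g.value(member, OWL.onProperty)
            if prop == v["hasValue"]:
                dr = g.value(member, OWL.someValuesFrom)
                facets = g.value(dr, OWL.withRestrictions)
                if facets is None:
                    offenders.append(f"{label}: value restriction without facets")
                    return None
                for facet in Collection(g, facets):
                    mini = g.value(facet, XSD.minInclusive)
                    maxi = g.value(facet, XSD.maxInclusive)
                    if mini is not None:
                        lo = float(mini)
                    if maxi is not None:
                        hi = float(maxi)
            elif prop == v["hasUnit"]:
                unit_node = g.value(member, OWL.someValuesFrom)
                unit = str(g.value(unit_node, RDFS.label) or unit_node)
        else:
            attr_name = str(g.value(member, RDFS.label) or member)
    if attr_name is None or (lo is None and hi is None):
        offenders.append(f"{label}: incomplete attribute restriction")
        return None
    if lo is not None and hi is not None:
        return AttributeRestriction(attr_name, "interval", lo=lo, hi=hi, unit=unit or "dalton")
    if hi is not None:
        return AttributeRestriction(attr_name, "le", hi=hi, unit=unit or "dalton")
    return AttributeRestriction(attr_name, "ge", lo=lo, unit=unit or "dalton")


def _pattern_from_label(label: str, kind: str) -> CanonicalPattern:
    """Reconstruct a registry pattern from its stored label and kind."""
    if kind == "smiles":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(label)
        if mol is not None:
            return smiles_pattern(mol, origin="fragment")
        return verbatim_pattern(label, origin="fragment")
    if kind == "smarts":
        pattern = _smarts_pattern_from_text(label)
        if pattern is not None:
            return pattern
    return verbatim_pattern(label, origin="predefined")


def _smarts_pattern_from_text(text: str) -> Optional[CanonicalPattern]:
    """Parse a canonical SMARTS text of this package back into a pattern."""
    from .canonical import canonicalize_smarts, isotope_table
    from .molgraph import AtomPrimitive

    table = isotope_table()
    prim_re = re.compile(r"\[[^\]]+\]")

    def to_iso(m: re.Match) -> str:
        prim = _parse_primitive(m.group(0))
        if prim is None:
            raise ValueError(m.group(0))
        return f"[{table.isotope(prim)}{_symbol(prim.element)}]"

    try:
        iso_smiles = prim_re.sub(to_iso, text)
    except ValueError:
        return None
    from rdkit import Chem

    mol = Chem.MolFromSmiles(iso_smiles, sanitize=False)
    if mol is None:
        return None
    from .molgraph import PatternGraph

    nodes = tuple(table.primitive(a.GetIsotope()) for a in mol.GetAtoms())
    edges = tuple((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), None) for b in mol.GetBonds())
    return canonicalize_smarts(PatternGraph(nodes, edges))


_PRIM_GENERIC_RE = re.compile(r"^\[#(\d+)(;a)?(;R)?\]$")
_PRIM_XH_RE = re.compile(r"^\[([A-Z][a-z]?)X(\d+)H(\d*)\]$")


def _symbol(z: int) -> str:
    from rdkit import Chem

    return Chem.GetPeriodicTable().GetElementSymbol(z)


def _parse_primitive(text: str):
    from rdkit import Chem

    from .molgraph import AtomPrimitive

    m = _PRIM_GENERIC_RE.match(text)
    if m:
        return AtomPrimitive(
            element=int(m.group(1)),
            aromatic=True if m.group(2) else None,
            ring=True if m.group(3) else None,
        )
    m = _PRIM_XH_RE.match(text)
    if m:
        z = Chem.GetPeriodicTable().GetAtomicNumber(m.group(1))
        return AtomPrimitive(
            element=z,
            aromatic=False,
            connectivity=int(m.group(2)),
            h_count=int(m.group(3) or 1),
        )
    return None
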