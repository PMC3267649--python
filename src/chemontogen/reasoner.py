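"""Self-organization: subsumption among class definitions and the inferred
class hierarchy.

A class A is subsumed by B exactly when A's conjunction entails B's: every
feature restriction of B appears in A with at least the same minimum count,
and every attribute clause of B is entailed by one of A's (interval
containment over the same attribute and unit).  Because shared features carry
identical hash-derived URIs, this structural test reproduces what a
description-logic reasoner infers from the generated OWL.  Mutually subsuming
definitions form equivalence groups; the hierarchy is the transitive reduction
of the subsumption preorder over those groups, rooted at 'molecular entity'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .axioms import ClassDefinition, Ontology, ROOT_CLASS_NAME, class_uri
from .canonical import pattern_contains


def is_subclass(a: ClassDefinition, b: ClassDefinition) -> bool:
    """True iff ``a`` entails ``b`` (a ⊑ b); reflexive by construction."""
    for uri, rb in b.restrictions.items():
        ra = a.restrictions.get(uri)
        if ra is None or ra.min_count < rb.min_count:
            return False
    for attr_b in b.attributes:
        if not any(attr_b.entailed_by(attr_a) for attr_a in a.attributes):
            return False
    return True


def equivalent(a: ClassDefinition, b: ClassDefinition) -> bool:
    return is_subclass(a, b) and is_subclass(b, a)


def subsume_by_implication(a: ClassDefinition, b: ClassDefinition, ont: Ontology) -> bool:
    """Extended mode: a restriction on a *more specific* pattern may satisfy a
    restriction on a more general one via pattern containment, even when the
    two classes' candidate pools were never cross-screened."""
    for uri_b, rb in b.restrictions.items():
        pb = ont.registry.pattern_for(uri_b)
        ok = False
        for uri_a, ra in a.restrictions.items():
            if ra.min_count < rb.min_count:
                continue
            if uri_a == uri_b:
                ok = True
                break
            pa = ont.registry.pattern_for(uri_a)
            if pa is not None and pb is not None and pattern_contains(pa, pb):
                ok = True
                break
        if not ok:
            return False
    for attr_b in b.attributes:
        if not any(attr_b.entailed_by(attr_a) for attr_a in a.attributes):
            return False
    return True


@dataclass
class Hierarchy:
    """Equivalence groups of class URIs with transitively reduced edges."""

    nodes: list[frozenset[str]]
    edges: set[tuple[frozenset[str], frozenset[str]]]  # (child group, parent group)
    root: frozenset[str]
    names: dict[str, str] = field(default_factory=dict)  # uri -> display name

    def group_of(self, uri: str) -> Optional[frozenset[str]]:
        for group in self.nodes:
            if uri in group:
                return group
        return None

    def strict_ancestors(self, uri: str) -> set[str]:
        """URIs of classes strictly above ``uri`` (excluding its own
        equivalence group and the root)."""
        start = self.group_of(uri)
        if start is None:
            return set()
        out: set[str] = set()
        frontier = [start]
        while frontier:
            g = frontier.pop()
            for child, parent in self.edges:
                if child == g and parent not in (self.root,) and parent != start:
                    if not out.issuperset(parent):
                        out |= set(parent)
                        frontier.append(parent)
        return out - set(start)

    def descendant_names(self, name: str) -> set[str]:
        """Display names of all classes strictly below the named class."""
        target = next((g for g in self.nodes if any(self.names.get(u) == name for u in g)), None)
        if target is None:
            return set()
        out: set[str] = set()
        frontier = [target]
        while frontier:
            g = frontier.pop()
            for child, parent in self.edges:
                if parent == g and child != target:
                    out |= {self.names.get(u, u) for u in child}
                    frontier.append(child)
        return out

    def edge_names(self) -> set[tuple[tuple[str, ...], tuple[str, ...]]]:
        """Edges as sorted tuples of display names, for exact comparisons."""

        def label(group: frozenset[str]) -> tuple[str, ...]:
            return tuple(sorted(self.names.get(u, u) for u in group))

        return {(label(c), label(p)) for c, p in self.edges}

    def to_json(self) -> str:
        data = {
            "nodes": [sorted(self.names.get(u, u) for u in g) for g in self.nodes],
            "edges": [
                [sorted(self.names.get(u, u) for u in c), sorted(self.names.get(u, u) for u in p)]
                for c, p in sorted(self.edges, key=str)
            ],
            "root": sorted(self.names.get(u, u) for u in self.root),
        }
        return json.dumps(data, indent=2, sort_keys=True)

    def to_dot(self) -> str:
        def label(group: frozenset[str]) -> str:
            return " = ".join(sorted(self.names.get(u, u) for u in group))

        lines = ["digraph hierarchy {", "  rankdir=BT;"]
        for c, p in sorted(self.edges, key=str):
            lines.append(f'  "{label(c)}" -> "{label(p)}";')
        lines.append("}")
        return "\n".join(lines)


def infer_hierarchy(ont: Ontology, mode: str = "strict") -> Hierarchy:
    """Compute equivalence groups, the full subsumption relation and its
    transitive reduction; classes with no inferred superclass attach to the
    root 'molecular entity'."""
    if mode not in {"strict", "implication"}:
        raise ValueError(f"unknown mode {mode!r}")
    subsumes = (
        is_subclass if mode == "strict" else (lambda a, b: subsume_by_implication(a, b, ont))
    )
    uris = sorted(ont.classes)
    g = nx.DiGraph()
    g.add_nodes_from(uris)
    for a in uris:
        for b in uris:
            if a != b and subsumes(ont.classes[a], ont.classes[b]):
                g.add_edge(a, b)  # a ⊑ b

    # merge equivalence groups (mutual subsumption = strongly connected)
    comp = list(nx.strongly_connected_components(g))
    group_of = {u: frozenset(c) for c in comp for u in c}
    dag = nx.DiGraph()
    dag.add_nodes_from(group_of[u] for u in uris)
    for a, b in g.edges:
        ga, gb = group_of[a], group_of[b]
        if ga != gb:
            dag.add_edge(ga, gb)
    reduced = nx.transitive_reduction(dag)

    root_uri = class_uri(ROOT_CLASS_NAME, ont.namespace)
    root = frozenset({root_uri})
    edges = set(reduced.edges)
    for node in reduced.nodes:
        if reduced.out_degree(node) == 0:
            edges.add((node, root))
    names = {uri: ont.classes[uri].name for uri in uris}
    names[root_uri] = ROOT_CLASS_NAME
    nodes = sorted(set(group_of.values()), key=lambda s: sorted(s)) + [root]
    return Hierarchy(nodes=nodes, edges=edges, root=root, names=names)
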