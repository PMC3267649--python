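"""Canonical forms for SMILES and SMARTS patterns, and pattern subsumption.

SMILES fragments are canonicalized directly.  SMARTS-level patterns have no
off-the-shelf canonicalizer, so each atomic primitive is mapped to a synthetic
isotope-tagged pseudo-atom (a distinct isotope per constraint combination —
e.g. a ring carbon and an aromatic carbon get different isotopes), the
pseudo-molecule is put through ordinary canonical-SMILES atom ordering, and the
isotope tokens are then translated back into SMARTS primitives via a lookup
table.  Because atomic mass participates in canonical atom ranking, the
resulting SMARTS text is invariant under any renumbering of the input graph.

``pattern_contains`` implements the "contains / is contained in" relation
between patterns that underlies principal characteristic substructures: an
injective, adjacency-preserving embedding in which every primitive of the
smaller pattern subsumes its image.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem

from .errors import CanonicalizationError
from .molgraph import AtomPrimitive, Molecule, PatternGraph, smiles_pattern_graph

_PT = Chem.GetPeriodicTable()

_ISOTOPE_BASE = 100
_MAX_ELEMENT = 118
_MAX_CONNECTIVITY = 6


def _universe() -> list[AtomPrimitive]:
    """The fixed, enumerable universe of primitives the framework can emit.

    Sorted by primitive text so isotope assignment is a pure function of the
    primitive, independent of which patterns a given run happens to produce.
    """
    prims: list[AtomPrimitive] = []
    for z in range(1, _MAX_ELEMENT + 1):
        prims.append(AtomPrimitive(element=z))
        prims.append(AtomPrimitive(element=z, aromatic=True))
        prims.append(AtomPrimitive(element=z, ring=True))
        for x in range(1, _MAX_CONNECTIVITY + 1):
            for h in range(1, x + 1):
                prims.append(
                    AtomPrimitive(element=z, aromatic=False, h_count=h, connectivity=x)
                )
    prims.sort(key=lambda p: p.text)
    return prims


class IsotopeTable:
    """Bijection between atomic primitives and synthetic isotope numbers."""

    def __init__(self) -> None:
        self._by_primitive: dict[AtomPrimitive, int] = {}
        self._by_isotope: dict[int, AtomPrimitive] = {}
        for rank, prim in enumerate(_universe()):
            iso = _ISOTOPE_BASE + rank
            self._by_primitive[prim] = iso
            self._by_isotope[iso] = prim

    def isotope(self, primitive: AtomPrimitive) -> int:
        try:
            return self._by_primitive[primitive]
        except KeyError:
            raise CanonicalizationError(
                f"primitive {primitive.text} is not expressible as a single pseudo-atom"
            ) from None

    def primitive(self, isotope: int) -> AtomPrimitive:
        try:
            return self._by_isotope[isotope]
        except KeyError:
            raise CanonicalizationError(f"unknown isotope token {isotope}") from None

    def used_entries(self, primitives: Iterable[AtomPrimitive]) -> list[tuple[int, str]]:
        return sorted({(self.isotope(p), p.text) for p in primitives})

    def write_sidecar(self, path: str | Path, primitives: Iterable[AtomPrimitive]) -> None:
        """TSV of (isotope token, SMARTS primitive) for the primitives in use."""
        lines = [f"{iso}\t{text}" for iso, text in self.used_entries(primitives)]
        Path(path).write_text("\n".join(lines) + "\n")


_TABLE = IsotopeTable()

_TOKEN_RE = re.compile(r"\[(\d+)([A-Z][a-z]?)\]")


@dataclass(frozen=True)
class CanonicalPattern:
    """A canonicalized pattern: unique text plus its graph.

    ``kind`` is ``smiles`` (explicit bond orders), ``smarts`` (abstracted
    primitives, any-bond semantics) or ``verbatim`` (predefined library entries
    with OR/recursive syntax that are matched but never canonicalized;
    ``graph`` is None for those).
    """

    kind: str
    text: str
    graph: Optional[PatternGraph] = field(compare=False)
    origin: str = field(default="fragment", compare=False)

    def __hash__(self) -> int:
        return hash(self.text)

    def __eq__(self, other) -> bool:
        return isinstance(other, CanonicalPattern) and self.text == other.text

    @property
    def canonicalizable(self) -> bool:
        return self.graph is not None


def canonical_smiles(mol: Molecule | Chem.Mol) -> str:
    """Canonical SMILES, invariant under atom reordering."""
    rdmol = mol.rdmol if isinstance(mol, Molecule) else mol
    return Chem.MolToSmiles(rdmol)


def smiles_pattern(mol: Molecule | Chem.Mol, origin: str = "fragment") -> CanonicalPattern:
    """Canonical SMILES-kind pattern for a (fragment) molecule."""
    rdmol = mol.rdmol if isinstance(mol, Molecule) else mol
    text = Chem.MolToSmiles(rdmol)
    # re-parse so the stored graph follows the canonical output order
    canon = Chem.MolFromSmiles(text, sanitize=True)
    if canon is None:  # pragma: no cover - canonical output always re-parses
        canon = rdmol
    return CanonicalPattern(kind="smiles", text=text, graph=smiles_pattern_graph(canon), origin=origin)


def _pseudo_molecule(graph: PatternGraph, table: IsotopeTable) -> Chem.Mol:
    rw = Chem.RWMol()
    for prim in graph.nodes:
        if prim.element is None:
            raise CanonicalizationError(
                f"primitive {prim.text} has no element and cannot be isotope-tagged"
            )
        atom = Chem.Atom(prim.element)
        atom.SetIsotope(table.isotope(prim))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, _order in graph.edges:
        # pseudo-molecule ordering treats all pattern bonds as single bonds;
        # the isotope trick orders atoms, not bonds
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def canonicalize_smarts(graph: PatternGraph, origin: str = "fragment") -> CanonicalPattern:
    """Canonical SMARTS-kind pattern via the isotope-relabeling procedure."""
    table = _TABLE
    pseudo = _pseudo_molecule(graph, table)
    iso_smiles = Chem.MolToSmiles(pseudo)
    text = _TOKEN_RE.sub(lambda m: table.primitive(int(m.group(1))).text, iso_smiles)
    # rebuild the graph in canonical output order from the isotopic SMILES
    reparsed = Chem.MolFromSmiles(iso_smiles, sanitize=False)
    if reparsed is None:  # pragma: no cover
        raise CanonicalizationError(f"internal: cannot re-parse {iso_smiles!r}")
    nodes = tuple(table.primitive(a.GetIsotope()) for a in reparsed.GetAtoms())
    edges = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), None) for b in reparsed.GetBonds()
    )
    return CanonicalPattern(kind="smarts", text=text, graph=PatternGraph(nodes, edges), origin=origin)


_BOND_TO_SMARTS = {None: "~", "-": "-", "=": "=", "#": "#", ":": ":"}


def query_smarts(graph: PatternGraph) -> str:
    """Executable SMARTS for a pattern graph with explicit bond primitives.

    The canonical display text writes bonds in the printed default-bond style
    ("[#6][#8]"), but abstracted patterns carry *any-bond* semantics (``~``)
    and SMILES-level patterns carry exact atoms and bond orders; this writer
    emits the explicit form the matcher executes.
    """
    n = len(graph)
    adj: dict[int, list[tuple[int, Optional[str]]]] = {i: [] for i in range(n)}
    for i, j, o in graph.edges:
        adj[i].append((j, o))
        adj[j].append((i, o))
    for neighbors in adj.values():
        neighbors.sort(key=lambda t: t[0])

    # first pass: spanning forest; non-tree edges become ring closures
    tree: set[frozenset[int]] = set()
    roots: list[int] = []
    seen: set[int] = set()
    for start in range(n):
        if start in seen:
            continue
        roots.append(start)
        seen.add(start)
        stack = [start]
        while stack:
            node = stack.pop()
            for other, _o in adj[node]:
                if other not in seen:
                    seen.add(other)
                    tree.add(frozenset((node, other)))
                    stack.append(other)
    closures: dict[frozenset[int], tuple[int, Optional[str]]] = {}
    num = 0
    for i, j, o in graph.edges:
        key = frozenset((i, j))
        if key not in tree:
            num += 1
            closures[key] = (num, o)

    def closure_token(ring_num: int, order: Optional[str]) -> str:
        sym = _BOND_TO_SMARTS[order]
        return f"{sym}%{ring_num:02d}" if ring_num > 9 else f"{sym}{ring_num}"

    def walk(node: int, parent: Optional[int]) -> str:
        out = [graph.nodes[node].text]
        for other, order in adj[node]:
            key = frozenset((node, other))
            if key in closures:
                ring_num, o = closures[key]
                out.append(closure_token(ring_num, o))
        children = [
            (other, order)
            for other, order in adj[node]
            if other != parent and frozenset((node, other)) in tree
        ]
        for idx, (other, order) in enumerate(children):
            sub = _BOND_TO_SMARTS[order] + walk(other, node)
            out.append(f"({sub})" if idx < len(children) - 1 else sub)
        return "".join(out)

    return ".".join(walk(r, None) for r in roots)


def verbatim_pattern(smarts: str, origin: str = "predefined") -> CanonicalPattern:
    """A predefined SMARTS entry kept verbatim (usable for matching only)."""
    return CanonicalPattern(kind="verbatim", text=smarts, graph=None, origin=origin)


def isotope_table() -> IsotopeTable:
    """The process-wide isotope lookup table."""
    return _TABLE


def primitive_subsumes(general: AtomPrimitive, specific: AtomPrimitive) -> bool:
    """True iff every atom satisfying ``specific`` satisfies ``general``.

    Dropping a constraint generalizes: an absent flag or H/X constraint on the
    general side subsumes any value on the specific side.
    """
    if general.element is not None and general.element != specific.element:
        return False
    if general.aromatic is not None and specific.aromatic != general.aromatic:
        return False
    if general.ring is not None and specific.ring != general.ring:
        return False
    if general.h_count is not None and specific.h_count != general.h_count:
        return False
    if general.connectivity is not None and specific.connectivity != general.connectivity:
        return False
    return True


def _edge_subsumes(general: Optional[str], specific: Optional[str]) -> bool:
    """Any-bond (None) subsumes every bond; an explicit order only itself."""
    return general is None or general == specific


def _adjacency(graph: PatternGraph) -> dict[int, dict[int, Optional[str]]]:
    adj: dict[int, dict[int, Optional[str]]] = {i: {} for i in range(len(graph))}
    for i, j, o in graph.edges:
        adj[i][j] = o
        adj[j][i] = o
    return adj


def pattern_contains(big: CanonicalPattern, small: CanonicalPattern) -> bool:
    """True iff ``small`` embeds into ``big`` so that any molecule matching
    ``big`` also matches ``small``.

    Exhaustive backtracking over injective node maps; patterns here are small
    (tens of nodes at most), so no heuristic matcher is needed.  Undefined
    (False) for verbatim patterns, which carry no graph.
    """
    if big.graph is None or small.graph is None:
        return False
    sg, bg = small.graph, big.graph
    if len(sg) > len(bg):
        return False
    sadj, badj = _adjacency(sg), _adjacency(bg)
    # order small nodes so each (after the first) touches an already-mapped one
    order: list[int] = []
    seen: set[int] = set()
    for start in range(len(sg)):
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        while stack:
            n = stack.pop()
            order.append(n)
            for m in sadj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def compatible(s: int, b: int) -> bool:
        if not primitive_subsumes(sg.nodes[s], bg.nodes[b]):
            return False
        for s2, o in sadj[s].items():
            if s2 in mapping:
                b2 = mapping[s2]
                if b2 not in badj[b] or not _edge_subsumes(o, badj[b][b2]):
                    return False
        return True

    def backtrack(k: int) -> bool:
        if k == len(order):
            return True
        s = order[k]
        for b in range(len(bg)):
            if b in used or not compatible(s, b):
                continue
            mapping[s] = b
            used.add(b)
            if backtrack(k + 1):
                return True
            del mapping[s]
            used.remove(b)
        return False

    return backtrack(0)
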