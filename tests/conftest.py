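"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-implement, by exhaustive enumeration, the
operations they check (fragment enumeration over all bond subsets, subgraph
embedding counting, connected maximum common subgraph) so the main code paths
are validated against a second, independent route.
"""

from __future__ import annotations

from itertools import combinations

import pytest
from rdkit import Chem

from chemontogen.canonical import CanonicalPattern
from chemontogen.molgraph import Atom, Molecule, PatternGraph, parse_structure

# --- molecule fixtures -------------------------------------------------------

SMALL_MOLECULES = {
    "methane": "C",
    "ethane": "CC",
    "ethanol": "CCO",
    "methanol": "CO",
    "water": "O",
    "ethylene_glycol": "OCCO",
    "glycerol": "OCC(O)CO",
    "propan_1_ol": "CCCO",
    "propan_2_ol": "CC(C)O",
    "allyl_alcohol": "OCC=C",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "cyclohexane": "C1CCCCC1",
    "methylamine": "CN",
    "methyl_acetate": "COC(C)=O",
    "acetic_acid": "CC(=O)O",
    "dimethyl_ether": "COC",
}


@pytest.fixture(scope="session")
def mols() -> dict[str, Molecule]:
    return {name: parse_structure(smi, identifier=name) for name, smi in SMALL_MOLECULES.items()}


@pytest.fixture(scope="session")
def alcohol_train() -> list[Molecule]:
    """The worked-example training set: five small organic alcohols."""
    return [
        parse_structure(s, identifier=s)
        for s in ["CO", "CCO", "CCCO", "CC(C)O", "OCc1ccccc1"]
    ]


# --- oracle: fragment enumeration over all bond subsets ----------------------


def oracle_fragment_smiles(mol: Molecule, max_cuts: int = 4, min_heavy: int = 1) -> set[str]:
    """Brute-force bond-subset fragment enumeration, independent of the
    fragmenter: own component search + from-scratch fragment reconstruction."""
    kek = mol.kekulized
    n = kek.GetNumAtoms()
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondType())
        for b in kek.GetBonds()
    ]
    out: set[str] = set()
    for k in range(0, min(max_cuts, len(bonds)) + 1):
        for cut in combinations(range(len(bonds)), k):
            kept = [bonds[i] for i in range(len(bonds)) if i not in cut]
            # own union-find over atoms
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, j, _t in kept:
                parent[find(i)] = find(j)
            comps: dict[int, list[int]] = {}
            for a in range(n):
                comps.setdefault(find(a), []).append(a)
            for atoms in comps.values():
                if len(atoms) < min_heavy:
                    continue
                rw = Chem.RWMol()
                index = {}
                for a in atoms:
                    src = kek.GetAtomWithIdx(a)
                    na = Chem.Atom(src.GetAtomicNum())
                    na.SetFormalCharge(src.GetFormalCharge())
                    index[a] = rw.AddAtom(na)
                for i, j, t in kept:
                    if i in index and j in index:
                        rw.AddBond(index[i], index[j], t)
                frag = rw.GetMol()
                try:
                    Chem.SanitizeMol(frag)
                except Exception:
                    continue
                out.add(Chem.MolToSmiles(frag))
    return out


# --- oracle: subgraph embedding enumeration -----------------------------------


def _atom_satisfies(prim, atom: Atom) -> bool:
    if prim.element is not None and prim.element != atom.element:
        return False
    if prim.aromatic is not None and atom.aromatic != prim.aromatic:
        return False
    if prim.ring is not None and atom.in_ring != prim.ring:
        return False
    if prim.h_count is not None and atom.h_count != prim.h_count:
        return False
    if prim.connectivity is not None and atom.degree + atom.h_count != prim.connectivity:
        return False
    return True


def oracle_count_embeddings(mol: Molecule, pattern: CanonicalPattern) -> int:
    """Brute-force distinct embedding count of a canonicalizable pattern.

    Enumerates every injective node map, checks primitive satisfaction and
    edge compatibility directly on the perceived atom/bond data, and collapses
    automorphic duplicates by matched atom set.  SMILES-kind single and double
    query bonds also match aromatic target bonds when the query bond is
    conjugated (mirroring the matcher's kekulized-fragment tolerance).
    """
    graph = pattern.graph
    assert graph is not None, "oracle needs a canonicalizable pattern"
    target_bonds = {}
    for b in mol.bonds:
        target_bonds[(b.i, b.j)] = b.order
        target_bonds[(b.j, b.i)] = b.order

    def edge_ok(order, ti: int, tj: int) -> bool:
        t_order = target_bonds.get((ti, tj))
        if t_order is None:
            return False
        return order is None or order == t_order

    n_small, n_big = len(graph), len(mol.atoms)
    found: set[frozenset[int]] = set()

    def backtrack(k: int, mapping: dict[int, int]) -> None:
        if k == n_small:
            found.add(frozenset(mapping.values()))
            return
        for t in range(n_big):
            if t in mapping.values():
                continue
            if not _atom_satisfies(graph.nodes[k], mol.atoms[t]):
                continue
            ok = True
            for i, j, order in graph.edges:
                if i == k and j in mapping:
                    ok = ok and edge_ok(order, t, mapping[j])
                elif j == k and i in mapping:
                    ok = ok and edge_ok(order, mapping[i], t)
                if not ok:
                    break
            if ok:
                mapping[k] = t
                backtrack(k + 1, mapping)
                del mapping[k]

    backtrack(0, {})
    return len(found)


# --- oracle: connected maximum common subgraph --------------------------------


def oracle_mcs_size(a: Molecule, b: Molecule) -> tuple[int, int]:
    """(atoms, bonds) of the largest connected common subgraph with exact
    elements and bond orders, by exhaustive search over connected bond subsets
    of the smaller molecule (plus single atoms)."""
    small, big = (a, b) if a.complexity <= b.complexity else (b, a)

    def embeds(atoms: list[int], bonds: list, target: Molecule) -> bool:
        prim_graph = PatternGraph(
            nodes=tuple(
                _exact_primitive(small.atoms[x]) for x in atoms
            ),
            edges=tuple(
                (atoms.index(i), atoms.index(j), o) for i, j, o in bonds
            ),
        )
        # kind "smarts" keeps the edge test order-exact (no conjugation parse)
        pat = CanonicalPattern(kind="smarts", text="<oracle>", graph=prim_graph)
        return oracle_count_embeddings(target, pat) > 0

    def _exact_primitive(atom: Atom):
        from chemontogen.molgraph import AtomPrimitive

        return AtomPrimitive(element=atom.element, aromatic=atom.aromatic)

    best = (0, 0)
    # single atoms
    for x in range(len(small.atoms)):
        if embeds([x], [], big):
            best = max(best, (1, 0))
    bonds = [(bd.i, bd.j, bd.order) for bd in small.bonds]
    for k in range(1, len(bonds) + 1):
        for sub in combinations(range(len(bonds)), k):
            chosen = [bonds[i] for i in sub]
            atoms = sorted({x for i, j, _o in chosen for x in (i, j)})
            # connectivity of chosen bond set
            parent = {x: x for x in atoms}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, j, _o in chosen:
                parent[find(i)] = find(j)
            if len({find(x) for x in atoms}) != 1:
                continue
            size = (len(atoms), len(chosen))
            if size <= best:
                continue
            if embeds(atoms, chosen, big):
                best = max(best, size)
    return best
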