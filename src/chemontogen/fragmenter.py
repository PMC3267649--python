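"""Candidate consensus features: bounded bond-cut fragments at every
abstraction level, plus the predefined pattern library and cross-class pool.

Fragmentation exhaustively cuts every combination of up to ``max_cuts`` bonds
(ring bonds included) and collects the resulting connected components.  The
same bond subsets drive both the native SMILES level (explicit bond orders, on
the kekulized parent so opened rings stay representable) and the seven
abstraction levels (primitives computed on the *parent's* perceived atom
states, so a mid-chain carbon exposed by a cut never masquerades as a CH3).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem

from .canonical import (
    CanonicalPattern,
    canonicalize_smarts,
    smiles_pattern,
    verbatim_pattern,
)
from .errors import FragmentLimitError
from .molgraph import AbstractionMode, Molecule, PatternGraph, abstract_molecule

logger = logging.getLogger(__name__)

_DEFAULT_LIBRARY = Path(__file__).parent / "data" / "default_patterns.smarts"


@dataclass(frozen=True)
class FragmentationSpec:
    """Bounds for bond-cut fragment enumeration."""

    max_cuts: int = 4
    min_heavy_atoms: int = 1
    cut_ring_bonds: bool = True
    max_fragments: int = 50_000  # per-molecule safety cap

    def __post_init__(self):
        if self.max_cuts < 0:
            raise ValueError("max_cuts must be >= 0")


@dataclass
class PatternLibrary:
    """A named collection of predefined patterns (e.g. curated SMARTS)."""

    name: str
    patterns: list[CanonicalPattern] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self):
        return len(self.patterns)


def _bond_subsets(mol: Molecule, spec: FragmentationSpec) -> Iterable[tuple[int, ...]]:
    cuttable = [
        idx
        for idx, b in enumerate(mol.bonds)
        if spec.cut_ring_bonds or not b.in_ring
    ]
    n = len(cuttable)
    total = sum(math.comb(n, k) for k in range(0, min(spec.max_cuts, n) + 1))
    if total > spec.max_fragments:
        raise FragmentLimitError(
            f"{mol.identifier or mol.source_smiles}: {total} bond subsets exceed the "
            f"cap of {spec.max_fragments}; reduce max_cuts or raise max_fragments"
        )
    for k in range(0, min(spec.max_cuts, n) + 1):
        yield from combinations(cuttable, k)


def _components_after_cuts(n_atoms: int, bonds: list[tuple[int, int]]) -> list[list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in range(n_atoms):
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        comps.append(sorted(comp))
    return comps


def enumerate_fragments(mol: Molecule, spec: FragmentationSpec = FragmentationSpec()) -> set[Molecule]:
    """All connected fragments obtainable by deleting up to ``max_cuts`` bonds.

    Open valences become implicit hydrogens; fragments are deduplicated by
    canonical SMILES.  Enumeration runs on the kekulized parent so fragments of
    aromatic rings remain valid structures (conjugated chains).
    """
    from .molgraph import Molecule as Mol  # local alias for constructor

    out: dict[str, Molecule] = {}
    kek = mol.kekulized
    for subset in _bond_subsets(mol, spec):
        rw = Chem.RWMol(kek)
        for bidx in sorted(subset, reverse=True):
            b = kek.GetBondWithIdx(bidx)
            rw.RemoveBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        m = rw.GetMol()
        try:
            m.UpdatePropertyCache(strict=False)
            frags = Chem.GetMolFrags(m, asMols=True, sanitizeFrags=False)
        except Exception:  # pragma: no cover - defensive
            continue
        for frag in frags:
            if frag.GetNumHeavyAtoms() < spec.min_heavy_atoms:
                continue
            frag = Chem.Mol(frag)
            try:
                Chem.SanitizeMol(frag)
            except Exception:
                continue
            smi = Chem.MolToSmiles(frag)
            if smi not in out:
                out[smi] = Mol.from_rdkit(frag, identifier=f"{mol.identifier}|{smi}", source_smiles=smi)
    return set(out.values())


def _abstract_fragment_graphs(mol: Molecule, mode: AbstractionMode, spec: FragmentationSpec) -> Iterable[PatternGraph]:
    """Fragment the abstracted parent graph over the same bond subsets."""
    whole = abstract_molecule(mol, mode)
    bond_pairs = [(b.i, b.j) for b in mol.bonds]
    for subset in _bond_subsets(mol, spec):
        removed = set(subset)
        kept = [bp for idx, bp in enumerate(bond_pairs) if idx not in removed]
        for comp in _components_after_cuts(len(mol.atoms), kept):
            if len(comp) < spec.min_heavy_atoms:
                continue
            index = {a: k for k, a in enumerate(comp)}
            nodes = tuple(whole.nodes[a] for a in comp)
            edges = tuple(
                (index[i], index[j], None)
                for i, j in kept
                if i in index and j in index
            )
            yield PatternGraph(nodes, edges)


def fragment_features(mol: Molecule, spec: FragmentationSpec = FragmentationSpec()) -> set[CanonicalPattern]:
    """Candidate features of one molecule: canonical SMILES fragments plus the
    canonical SMARTS of its fragments at each of the seven abstraction modes."""
    features: set[CanonicalPattern] = set()
    for frag in enumerate_fragments(mol, spec):
        features.add(smiles_pattern(frag, origin="fragment"))
    seen_graph_texts: set[str] = set()
    for mode in AbstractionMode:
        for graph in _abstract_fragment_graphs(mol, mode, spec):
            pat = canonicalize_smarts(graph, origin="fragment")
            if pat.text not in seen_graph_texts:
                seen_graph_texts.add(pat.text)
                features.add(pat)
    return features


def load_pattern_library(path: str | Path | None = None) -> PatternLibrary:
    """Load a predefined SMARTS library (one pattern per line, ``#`` comments).

    Entries with OR/recursive syntax are kept verbatim (matchable but not
    canonicalizable); unparsable entries are logged and skipped.
    """
    if path is None:
        path = _DEFAULT_LIBRARY
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    patterns: dict[str, CanonicalPattern] = {}
    skipped = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        # '#' begins a comment only at line start or after whitespace
        # (SMARTS itself uses '#' for atomic numbers, e.g. [#6])
        if line.lstrip().startswith("#"):
            continue
        entry = re.split(r"\s#", line, maxsplit=1)[0].strip()
        if not entry:
            continue
        q = Chem.MolFromSmarts(entry)
        if q is None:
            skipped += 1
            logger.warning("skipping unparsable SMARTS %r (line %d of %s)", entry, lineno, path)
            continue
        pat = verbatim_pattern(entry, origin="predefined")
        patterns.setdefault(pat.text, pat)
    if skipped:
        logger.warning("%d unparsable librar{y,ies} entr(y/ies) skipped in %s", skipped, path)
    return PatternLibrary(name=path.stem, patterns=list(patterns.values()), provenance=str(path))


def candidate_pool(
    training: list[Molecule],
    library: Optional[PatternLibrary] = None,
    cross_class: Iterable[CanonicalPattern] = (),
    spec: FragmentationSpec = FragmentationSpec(),
) -> set[CanonicalPattern]:
    """Union of member fragment features, the predefined library and any
    cross-class consensus patterns, deduplicated by canonical text."""
    if not training:
        raise ValueError("empty training set")
    pool: set[CanonicalPattern] = set()
    for mol in training:
        pool |= fragment_features(mol, spec)
    if library is not None:
        pool |= set(library.patterns)
    pool |= set(cross_class)
    return pool
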