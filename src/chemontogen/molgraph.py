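"""Molecular data model, structure input and the seven-level atom abstraction.

Molecules are heavy-atom graphs with perceived aromaticity, ring membership and
implicit hydrogen counts.  Every generated pattern in the framework starts from
an *abstraction* of these atoms: a SMARTS-style atomic primitive that keeps only
a chosen subset of the atom's attributes (element, aromaticity, ring membership,
or the full hydrogenation state of a terminal atom such as CH3 or OH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import SmilesParseError, StructureError

logger = logging.getLogger(__name__)

# RDKit writes parse diagnostics to the C++ log stream; we report errors through
# exceptions instead, so silence the duplicate console output.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

_PT = Chem.GetPeriodicTable()

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


class AbstractionMode(Enum):
    """The seven atom-abstraction levels used for pattern generation.

    Single attributes: general atom type, aromaticity, ring membership, full
    hydrogenation state; plus the binary combinations of full hydrogenation
    with each of the other three.
    """

    GENERIC = "generic"
    AROMATIC = "aromatic"
    RING = "ring"
    FULL_H = "full_h"
    AROMATIC_FULL_H = "aromatic_full_h"
    RING_FULL_H = "ring_full_h"
    GENERIC_FULL_H = "generic_full_h"


_FULL_H_MODES = {
    AbstractionMode.FULL_H,
    AbstractionMode.AROMATIC_FULL_H,
    AbstractionMode.RING_FULL_H,
    AbstractionMode.GENERIC_FULL_H,
}

# Base mode applied to atoms that are not fully hydrogenated.
_BASE_MODE = {
    AbstractionMode.GENERIC: AbstractionMode.GENERIC,
    AbstractionMode.AROMATIC: AbstractionMode.AROMATIC,
    AbstractionMode.RING: AbstractionMode.RING,
    AbstractionMode.FULL_H: AbstractionMode.GENERIC,
    AbstractionMode.AROMATIC_FULL_H: AbstractionMode.AROMATIC,
    AbstractionMode.RING_FULL_H: AbstractionMode.RING,
    AbstractionMode.GENERIC_FULL_H: AbstractionMode.GENERIC,
}


@dataclass(frozen=True)
class Atom:
    """A perceived heavy atom."""

    index: int
    element: int
    aromatic: bool
    in_ring: bool
    ring_count: int
    h_count: int
    charge: int
    degree: int

    @property
    def fully_hydrogenated(self) -> bool:
        """True for terminal atoms whose free valences are all hydrogens.

        A terminal atom in a chain (heavy-atom degree <= 1) carrying at least
        one hydrogen, e.g. the carbon of a CH3 group or the oxygen of an OH.
        """
        return self.degree <= 1 and self.h_count >= 1


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str  # one of '-', '=', '#', ':'
    in_ring: bool


@dataclass(frozen=True)
class AtomPrimitive:
    """A SMARTS atomic expression restricted to the constraint kinds the
    framework generates: element, aromatic flag, ring flag, and the exact
    H-count/connectivity pair of a fully hydrogenated terminal atom."""

    element: Optional[int] = None
    aromatic: Optional[bool] = None
    ring: Optional[bool] = None
    h_count: Optional[int] = None
    connectivity: Optional[int] = None

    def __post_init__(self):
        if (
            self.element is None
            and self.aromatic is None
            and self.ring is None
            and self.h_count is None
            and self.connectivity is None
        ):
            raise ValueError("empty atom primitive")

    @property
    def text(self) -> str:
        """Canonical SMARTS atomic expression for this constraint set."""
        if self.h_count is not None:
            sym = _PT.GetElementSymbol(self.element)
            h = "H" if self.h_count == 1 else f"H{self.h_count}"
            return f"[{sym}X{self.connectivity}{h}]"
        parts = [f"#{self.element}" if self.element is not None else "*"]
        if self.aromatic is True:
            parts.append("a")
        elif self.aromatic is False:
            parts.append("A")
        if self.ring is True:
            parts.append("R")
        return "[" + ";".join(parts) + "]"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class PatternGraph:
    """Topology + atomic primitives of a pattern.

    ``edges`` entries are ``(i, j, order)`` where ``order`` is a bond symbol
    for SMILES-level patterns and ``None`` ("any bond") for abstracted
    SMARTS-level patterns.
    """

    nodes: tuple[AtomPrimitive, ...]
    edges: tuple[tuple[int, int, Optional[str]], ...]

    def __len__(self) -> int:
        return len(self.nodes)

    def neighbors(self, i: int) -> list[tuple[int, Optional[str]]]:
        out = []
        for a, b, o in self.edges:
            if a == i:
                out.append((b, o))
            elif b == i:
                out.append((a, o))
        return out


@dataclass(eq=False)  # identity semantics: hashable, usable in sets
class Molecule:
    """Heavy-atom graph with perception results and the originating SMILES."""

    atoms: list[Atom]
    bonds: list[Bond]
    identifier: str
    source_smiles: str
    rdmol: Chem.Mol = field(repr=False)
    kekulized: Chem.Mol = field(repr=False)

    @property
    def num_heavy_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    @property
    def complexity(self) -> int:
        """Heavy atoms + bonds; the partitioning order for training sets."""
        return len(self.atoms) + len(self.bonds)

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, identifier: str = "", source_smiles: str = "") -> "Molecule":
        ring_info = mol.GetRingInfo()
        atoms = [
            Atom(
                index=a.GetIdx(),
                element=a.GetAtomicNum(),
                aromatic=a.GetIsAromatic(),
                in_ring=a.IsInRing(),
                ring_count=ring_info.NumAtomRings(a.GetIdx()),
                h_count=a.GetTotalNumHs(),
                charge=a.GetFormalCharge(),
                degree=a.GetDegree(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            Bond(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=_BOND_SYMBOL[b.GetBondType()],
                in_ring=b.IsInRing(),
            )
            for b in mol.GetBonds()
        ]
        kek = Chem.Mol(mol)
        try:
            Chem.Kekulize(kek, clearAromaticFlags=True)
        except Chem.KekulizeException:  # pragma: no cover - degenerate input
            kek = Chem.Mol(mol)
        return cls(
            atoms=atoms,
            bonds=bonds,
            identifier=identifier,
            source_smiles=source_smiles or Chem.MolToSmiles(mol),
            rdmol=mol,
            kekulized=kek,
        )


def _syntax_check(smiles: str) -> None:
    """Best-effort localization of SMILES syntax errors (brackets/parens)."""
    depth = 0
    bracket = None
    for pos, ch in enumerate(smiles):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SmilesParseError(smiles, "unmatched ')'", pos)
        elif ch == "[":
            if bracket is not None:
                raise SmilesParseError(smiles, "nested '['", pos)
            bracket = pos
        elif ch == "]":
            if bracket is None:
                raise SmilesParseError(smiles, "unmatched ']'", pos)
            bracket = None
    if depth > 0:
        raise SmilesParseError(smiles, "unclosed '('", smiles.rindex("("))
    if bracket is not None:
        raise SmilesParseError(smiles, "unclosed '['", bracket)


def parse_structure(smiles: str, identifier: str = "") -> Molecule:
    """Parse a SMILES string into a perceived :class:`Molecule`.

    Raises :class:`SmilesParseError` on malformed input (naming the offending
    token position when it can be localized) and :class:`StructureError` on
    chemically invalid structures such as valence violations.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty input")
    _syntax_check(smiles)
    raw = Chem.MolFromSmiles(smiles, sanitize=False)
    if raw is None:
        raise SmilesParseError(smiles, "not a valid SMILES string")
    try:
        Chem.SanitizeMol(raw)
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError) as exc:
        raise StructureError(f"invalid structure {smiles!r}: {exc}") from exc
    return Molecule.from_rdkit(raw, identifier=identifier, source_smiles=smiles)


def read_structures(path: str | Path, fmt: Optional[str] = None) -> list[Molecule]:
    """Read molecules from a ``.smi`` (``SMILES<ws>ID`` per line) or SDF file.

    Records that fail to parse are skipped with a logged warning; raises if the
    file is unreadable or contains zero parsable records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smi"
    molecules: list[Molecule] = []
    skipped = 0
    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"{path.stem}-{lineno}"
            try:
                molecules.append(parse_structure(smiles, identifier=ident))
            except (SmilesParseError, StructureError) as exc:
                skipped += 1
                logger.warning("skipping line %d of %s: %s", lineno, path, exc)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("skipping unparsable SDF record %d of %s", i + 1, path)
                continue
            ident = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}-{i + 1}"
            molecules.append(Molecule.from_rdkit(mol, identifier=ident))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not molecules:
        raise StructureError(f"no parsable records in {path} ({skipped} skipped)")
    if skipped:
        logger.warning("%d record(s) skipped while reading %s", skipped, path)
    return molecules


def abstract_atom(atom: Atom, mode: AbstractionMode) -> AtomPrimitive:
    """Abstract one atom to the primitive of the requested mode.

    FULL_H modes encode the exact hydrogen count and total connectivity of a
    fully hydrogenated terminal atom (the SMARTS ``X``/``H`` primitives, e.g.
    ``[OX2H]``); for any other atom they fall back to the non-H base mode.
    """
    if mode in _FULL_H_MODES and atom.fully_hydrogenated:
        return AtomPrimitive(
            element=atom.element,
            aromatic=False,
            h_count=atom.h_count,
            connectivity=atom.degree + atom.h_count,
        )
    base = _BASE_MODE[mode]
    if base is AbstractionMode.AROMATIC and atom.aromatic:
        return AtomPrimitive(element=atom.element, aromatic=True)
    if base is AbstractionMode.RING and atom.in_ring:
        return AtomPrimitive(element=atom.element, ring=True)
    return AtomPrimitive(element=atom.element)


def abstract_molecule(mol: Molecule, mode: AbstractionMode) -> PatternGraph:
    """Replace every atom by its abstraction; bonds become "any bond"."""
    nodes = tuple(abstract_atom(a, mode) for a in mol.atoms)
    edges = tuple((b.i, b.j, None) for b in mol.bonds)
    return PatternGraph(nodes=nodes, edges=edges)


def smiles_pattern_graph(mol: Chem.Mol) -> PatternGraph:
    """Pattern graph of a SMILES-level fragment: exact elements and
    aromaticity with explicit bond orders."""
    nodes = tuple(
        AtomPrimitive(element=a.GetAtomicNum(), aromatic=a.GetIsAromatic())
        for a in mol.GetAtoms()
    )
    edges = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_SYMBOL[b.GetBondType()])
        for b in mol.GetBonds()
    )
    return PatternGraph(nodes=nodes, edges=edges)


def compute_molecular_weight(mol: Molecule) -> float:
    """Average molecular weight in Daltons, implicit hydrogens included."""
    return float(Descriptors.MolWt(mol.rdmol))


def largest_component(mol: Molecule) -> Molecule:
    """The connected component with the most heavy atoms (salt stripping).

    Ties are broken by larger molecular weight, then by canonical SMILES
    order.  A warning is logged when anything is stripped.
    """
    if mol.num_heavy_atoms == 0:
        raise StructureError("empty molecule")
    frags = Chem.GetMolFrags(mol.rdmol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    keyed = sorted(
        frags,
        key=lambda f: (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f)),
    )
    kept = keyed[0]
    logger.warning(
        "stripped %d component(s) from %s, keeping %s",
        len(frags) - 1,
        mol.identifier or mol.source_smiles,
        Chem.MolToSmiles(kept),
    )
    return Molecule.from_rdkit(kept, identifier=mol.identifier, source_smiles=Chem.MolToSmiles(kept))
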