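"""Consensus fingerprints, principal characteristic substructures and
training/test partitioning.

A feature is *consensus* for a class when its presence fraction over the
training set is exactly 1.0.  The candidate pool combines bounded fragmentation
at all abstraction levels, the predefined library, optional cross-class
patterns, and maximum-common-substructure analysis of the smallest class
members (including one second-order MCS-of-MCS round).  The consensus features
that contain, but are not contained in, other consensus features are the
class's principal characteristic substructures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import rdFMCS

from . import classifier
from .canonical import CanonicalPattern, canonical_smiles, pattern_contains, smiles_pattern
from .fragmenter import FragmentationSpec, PatternLibrary, candidate_pool, fragment_features
from .molgraph import Molecule, parse_structure

logger = logging.getLogger(__name__)


@dataclass
class TrainingPartition:
    """Least-complex members for training, the rest for testing."""

    train: list[Molecule]
    test: list[Molecule]


def partition_class(members: list[Molecule], k: int = 5) -> TrainingPartition:
    """Sort by complexity (heavy atoms + bonds, ties by canonical SMILES) and
    put the ``k`` least complex members in the training set.

    The smallest class members have to contain every consensus pattern the
    rest of the class contains, so they suffice for derivation.
    """
    if not members:
        raise ValueError("empty member list")
    ordered = sorted(members, key=lambda m: (m.complexity, canonical_smiles(m)))
    if len(ordered) <= k:
        return TrainingPartition(train=ordered, test=[])
    return TrainingPartition(train=ordered[:k], test=ordered[k:])


def feature_fraction(feature: CanonicalPattern, mols: list[Molecule]) -> float:
    """Fraction of molecules containing at least one match of the feature."""
    if not mols:
        raise ValueError("empty molecule list")
    hits = sum(1 for m in mols if classifier.has_match(m, feature))
    return hits / len(mols)


@dataclass
class ConsensusFingerprint:
    """The set of features present in every training member of a class."""

    class_name: str
    features: set[CanonicalPattern] = field(default_factory=set)
    principal: set[CanonicalPattern] = field(default_factory=set)
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.features

    def feature_texts(self) -> set[str]:
        return {p.text for p in self.features}


def _mcs_of_pair(a: Molecule, b: Molecule) -> Optional[CanonicalPattern]:
    """Connected maximum common substructure with element-exact atoms and
    order-exact bonds (aromatic matches aromatic), as a SMILES-kind pattern."""
    res = rdFMCS.FindMCS(
        [a.rdmol, b.rdmol],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        timeout=10,
    )
    if res.canceled or res.numAtoms == 0:
        return None
    query = Chem.MolFromSmarts(res.smartsString)
    match = a.rdmol.GetSubstructMatch(query)
    if not match:
        return None
    bond_ids = []
    for qb in query.GetBonds():
        i, j = match[qb.GetBeginAtomIdx()], match[qb.GetEndAtomIdx()]
        bond = a.rdmol.GetBondBetweenAtoms(i, j)
        if bond is not None:
            bond_ids.append(bond.GetIdx())
    if bond_ids:
        submol = Chem.PathToSubmol(a.rdmol, bond_ids)
    else:  # single-atom MCS
        submol = Chem.MolFromSmiles(
            Chem.MolFragmentToSmiles(a.rdmol, atomsToUse=[match[0]])
        )
    try:
        submol = Chem.Mol(submol)
        Chem.SanitizeMol(submol)
    except Exception:
        logger.debug("MCS submol of (%s, %s) not SMILES-representable; skipped", a.identifier, b.identifier)
        return None
    return smiles_pattern(submol, origin="mcs")


def pairwise_mcs(mols: list[Molecule], k: int = 5) -> set[CanonicalPattern]:
    """MCS of every unordered pair among the ``k`` least complex molecules."""
    if len(mols) < 2:
        raise ValueError("pairwise MCS needs at least two molecules")
    smallest = sorted(mols, key=lambda m: (m.complexity, canonical_smiles(m)))[:k]
    out: set[CanonicalPattern] = set()
    for a, b in combinations(smallest, 2):
        pat = _mcs_of_pair(a, b)
        if pat is not None:
            out.add(pat)
    return out


def mcs_closure(
    seeds: set[CanonicalPattern],
    spec: FragmentationSpec = FragmentationSpec(),
) -> set[CanonicalPattern]:
    """Seeds, plus one round of MCS-of-MCS (seeds treated as molecules), plus
    the fragment features of every closure member.

    A single second-order pass: even when no training member is itself the
    minimal representative (e.g. three different aniline derivatives), the
    shared scaffold — the bare ring — still surfaces.
    """
    closure: set[CanonicalPattern] = set(seeds)
    seed_mols = [parse_structure(p.text, identifier=f"mcs:{p.text}") for p in seeds if p.kind == "smiles"]
    if len(seed_mols) >= 2:
        for a, b in combinations(seed_mols, 2):
            pat = _mcs_of_pair(a, b)
            if pat is not None:
                closure.add(pat)
    for pat in list(closure):
        if pat.kind != "smiles":
            continue
        mol = parse_structure(pat.text, identifier=f"mcs:{pat.text}")
        closure |= fragment_features(mol, spec)
    return closure


def principal_substructures(features: set[CanonicalPattern] | "ConsensusFingerprint") -> set[CanonicalPattern]:
    """Maximal elements under pattern containment: consensus features contained
    in no other distinct consensus feature.

    Verbatim library patterns carry no graph, so containment is undefined for
    them; they participate in definitions but not in maximality comparisons.
    """
    if isinstance(features, ConsensusFingerprint):
        features = features.features
    comparable = [f for f in features if f.canonicalizable]
    principal: set[CanonicalPattern] = set()
    for f in comparable:
        contained = any(
            g.text != f.text and pattern_contains(g, f) for g in comparable
        )
        if not contained:
            principal.add(f)
    return principal


def consensus_fingerprint(
    partition: TrainingPartition,
    library: Optional[PatternLibrary] = None,
    cross_class: Iterable[CanonicalPattern] = (),
    class_name: str = "",
    spec: FragmentationSpec = FragmentationSpec(),
    k: int = 5,
) -> ConsensusFingerprint:
    """Derive the consensus fingerprint of a class from its training set.

    Candidates with a presence fraction below exactly 1.0 on the training set
    are discarded (no tolerance).  An empty result is returned with a logged
    convergence warning rather than raising.
    """
    train = partition.train
    if not train:
        raise ValueError("empty training set")
    pool = candidate_pool(train, library, cross_class, spec)
    if len(train) >= 2:
        pool |= mcs_closure(pairwise_mcs(train, k=k), spec)
    fractions = {p.text: feature_fraction(p, train) for p in pool}
    features = {p for p in pool if fractions[p.text] == 1.0}
    fp = ConsensusFingerprint(
        class_name=class_name,
        features=features,
        fractions={p.text: 1.0 for p in features},
    )
    fp.principal = principal_substructures(features)
    if fp.empty:
        logger.warning("class %s: no consensus feature (empty fingerprint)", class_name or "<unnamed>")
    return fp


@dataclass
class ConvergenceReport:
    """Diagnostics for curation errors in the training set."""

    class_name: str
    empty_fingerprint: bool
    only_single_atom_principals: bool
    expected_text: Optional[str] = None
    expected_present: Optional[bool] = None
    non_matching_members: list[str] = field(default_factory=list)

    @property
    def suspicious(self) -> bool:
        return (
            self.empty_fingerprint
            or self.only_single_atom_principals
            or self.expected_present is False
        )


def convergence_report(
    fp: ConsensusFingerprint,
    partition: TrainingPartition,
    expected: Optional[CanonicalPattern] = None,
) -> ConvergenceReport:
    """Flag non-convergence and identify curation-error suspects.

    When an expected pattern is supplied and absent from the fingerprint, the
    training members that fail to match it are listed — in the published ester
    anomaly this is how the erroneous N-linked member was found.
    """
    single_atom_only = bool(fp.principal) and all(
        p.graph is not None and len(p.graph) == 1 for p in fp.principal
    )
    report = ConvergenceReport(
        class_name=fp.class_name,
        empty_fingerprint=fp.empty,
        only_single_atom_principals=single_atom_only,
    )
    if expected is not None:
        report.expected_text = expected.text
        report.expected_present = expected.text in fp.feature_texts() or any(
            f.canonicalizable and expected.canonicalizable and
            pattern_contains(f, expected) and pattern_contains(expected, f)
            for f in fp.features
        )
        if not report.expected_present:
            report.non_matching_members = [
                m.identifier or m.source_smiles
                for m in partition.train
                if not classifier.has_match(m, expected)
            ]
    return report
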