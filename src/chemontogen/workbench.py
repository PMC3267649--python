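"""Fixture generation and end-to-end pipeline orchestration.

The fixture generator produces small homologous series (alcohols, diols,
triols, primary amines, carboxylic acids, esters, ethers, benzenes) with a
known nested hierarchy, so the whole framework can be exercised without any
external data.  Each family combines fixed *anchor* members — chosen so the
family's consensus is pinned to its defining chemistry (e.g. methanol plus
benzyl alcohol for alcohols, which keeps incidental features like a shared
methyl group out of the consensus) — with seed-selected extras from a template
pool.  Family membership is guaranteed by construction and re-verified with
the classifier's matcher.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .axioms import (
    AttributeRestriction,
    ClassDefinition,
    DEFAULT_NAMESPACE,
    FunctionalGroupRegistry,
    Ontology,
    build_class_definition,
    to_manchester,
    write_owl,
)
from .canonical import CanonicalPattern, isotope_table, smiles_pattern, verbatim_pattern
from .classifier import (
    ClassificationReport,
    classify_entity,
    count_distinct_matches,
    entity_fingerprint,
    evaluate,
)
from .consensus import (
    ConsensusFingerprint,
    ConvergenceReport,
    TrainingPartition,
    consensus_fingerprint,
    convergence_report,
    partition_class,
)
from .errors import ChemontogenError, SmilesParseError, StructureError
from .fragmenter import FragmentationSpec, load_pattern_library
from .molgraph import Molecule, largest_component, parse_structure
from .reasoner import Hierarchy, infer_hierarchy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeriesSpec:
    """A synthetic homologous series request."""

    family: str
    count: int = 5
    size_range: tuple[int, int] = (1, 12)  # heavy atoms
    corruption: Optional[str] = None  # e.g. "n_linked" for esters

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


# anchors pin each family's consensus; pools supply seed-selected extras
_FAMILIES: dict[str, dict] = {
    "alcohols": {
        # methanol bounds the consensus from below; allyl alcohol is a small
        # methyl-free member, keeping an incidental shared CH3 out of it
        "anchors": ["CO", "OCC=C"],
        "pool": ["CCO", "CCCO", "CC(C)O", "CCCCO", "CC(C)CO", "CCC(C)O", "CCCCCO", "CC(O)CC", "OCc1ccccc1"],
        "validator": ("[#6][OX2H]", 1, "min"),
    },
    "diols": {
        "anchors": ["OCCO", "OCCCO"],
        "pool": ["OCC(C)O", "OCCCCO", "CC(O)C(C)O", "OCC(C)CO", "OCCC(C)O", "OCCCCCO"],
        "validator": ("[#6][OX2H]", 2, "exact"),
    },
    "triols": {
        "anchors": ["OCC(O)CO", "OCC(CO)CO"],
        # pool members all share the 1,3-dioxy backbone of the anchors, so
        # held-out members still satisfy the derived definition
        "pool": ["CC(O)C(O)CO", "OCC(O)CCO", "OCC(C)(O)CO", "OCCC(O)CCO", "CC(O)CC(O)CO"],
        "validator": ("[#6][OX2H]", 3, "exact"),
    },
    "amines": {
        "anchors": ["CN", "CCN"],
        "pool": ["CCCN", "CC(C)N", "CCCCN", "CC(C)CN", "CCC(C)N"],
        "validator": ("[NX3H2]", 1, "min"),
    },
    "carboxylic acids": {
        "anchors": ["OC=O", "CC(=O)O"],
        "pool": ["CCC(=O)O", "CCCC(=O)O", "CC(C)C(=O)O", "CCCCC(=O)O"],
        "validator": ("C(=O)[OX2H]", 1, "min"),
    },
    "esters": {
        "anchors": ["COC=O", "CCOC(C)=O"],
        "pool": ["CCOC=O", "COC(C)=O", "CCC(=O)OC", "CCOC(=O)CC", "CCCOC=O"],
        "validator": ("C(=O)O[#6]", 1, "min"),
    },
    "ethers": {
        "anchors": ["COC", "CCOCC"],
        "pool": ["CCOC", "CCCOC", "CC(C)OC", "CCCOCC", "CCCCOC"],
        "validator": ("[#6][OX2H0][#6]", 1, "min"),
    },
    "benzenes": {
        "anchors": ["c1ccccc1", "Cc1ccccc1"],
        "pool": ["CCc1ccccc1", "Cc1ccccc1C", "CCCc1ccccc1", "Cc1ccc(C)cc1"],
        "validator": ("c1ccccc1", 1, "min"),
    },
}

_CORRUPTIONS: dict[tuple[str, str], str] = {
    # an N-linked pseudo-ester (RC(=O)ONR) — the published curation-error case
    ("esters", "n_linked"): "CC(=O)ONC",
}


def generate_series(spec: SeriesSpec, seed: int = 0) -> list[Molecule]:
    """Deterministic synthetic members of one family for a fixed seed."""
    family = _FAMILIES.get(spec.family)
    if family is None:
        raise ValueError(f"unrecognized family {spec.family!r} (known: {sorted(_FAMILIES)})")
    rng = random.Random(f"{seed}:{spec.family}")
    lo, hi = spec.size_range
    anchors = list(family["anchors"])
    pool = [
        s
        for s in family["pool"]
        if lo <= parse_structure(s).num_heavy_atoms <= hi
    ]
    chosen = anchors[: spec.count]
    extra_needed = spec.count - len(chosen)
    if extra_needed > 0:
        chosen += rng.sample(pool, min(extra_needed, len(pool)))
    members = [
        parse_structure(smi, identifier=f"{spec.family.replace(' ', '_')}-{i + 1}")
        for i, smi in enumerate(chosen)
    ]
    smarts, n, mode = family["validator"]
    probe = verbatim_pattern(smarts)
    for mol in members:
        got = count_distinct_matches(mol, probe)
        ok = got >= n if mode == "min" else got == n
        if not ok:  # pragma: no cover - template invariant
            raise ChemontogenError(f"{mol.identifier}: fails {spec.family} validator {smarts} (got {got})")
    if spec.corruption is not None:
        smi = _CORRUPTIONS.get((spec.family, spec.corruption))
        if smi is None:
            raise ValueError(f"no corruption {spec.corruption!r} for family {spec.family!r}")
        members.append(
            parse_structure(smi, identifier=f"{spec.family.replace(' ', '_')}-corrupt-{spec.corruption}")
        )
    return members


def family_names() -> list[str]:
    return sorted(_FAMILIES)


@dataclass
class RunConfig:
    """Settings for one pipeline run; the seed governs fixture generation only
    (every analytic stage is deterministic)."""

    outdir: Optional[Path] = None
    namespace: str = DEFAULT_NAMESPACE
    max_cuts: int = 4
    pattern_library: Optional[Path] = None  # None = packaged default
    use_library: bool = True
    k: int = 5
    mode: str = "strict"  # or "implication"
    cross_class_screening: bool = False
    strip_salts: bool = True
    aromaticity_model: str = "rdkit-default"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if kwargs.get("outdir"):
            kwargs["outdir"] = Path(kwargs["outdir"])
        if kwargs.get("pattern_library"):
            kwargs["pattern_library"] = Path(kwargs["pattern_library"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        # outdir is deliberately omitted: artifacts are byte-identical across
        # repeated runs with the same config and seed, wherever they land
        return {
            "namespace": self.namespace,
            "max_cuts": self.max_cuts,
            "pattern_library": str(self.pattern_library) if self.pattern_library else "packaged-default",
            "use_library": self.use_library,
            "k": self.k,
            "mode": self.mode,
            "cross_class_screening": self.cross_class_screening,
            "strip_salts": self.strip_salts,
            "aromaticity_model": self.aromaticity_model,
            "seed": self.seed,
        }


@dataclass
class ClassSpec:
    """One class to derive: curated members plus curator-supplied overrides."""

    name: str
    members: list[Molecule]
    cardinality_overrides: dict[str, int] = field(default_factory=dict)
    attribute_restrictions: list[AttributeRestriction] = field(default_factory=list)
    expected: Optional[str] = None  # expected pattern (SMILES or SMARTS)
    train_override: Optional[list[str]] = None  # explicit train member ids


@dataclass
class PipelineResult:
    ontology: Ontology
    hierarchy: Hierarchy
    fingerprints: dict[str, ConsensusFingerprint]
    partitions: dict[str, TrainingPartition]
    convergence: dict[str, ConvergenceReport]
    definitions: dict[str, ClassDefinition]
    report: ClassificationReport
    evaluation: dict
    manifest: dict


def _expected_pattern(text: str) -> CanonicalPattern:
    try:
        return smiles_pattern(parse_structure(text).rdmol, origin="fragment")
    except (SmilesParseError, StructureError):
        return verbatim_pattern(text)


def _partition(spec: ClassSpec, k: int, strip: bool) -> TrainingPartition:
    members = [largest_component(m) if strip else m for m in spec.members]
    if spec.train_override is not None:
        wanted = set(spec.train_override)
        train = [m for m in members if m.identifier in wanted]
        test = [m for m in members if m.identifier not in wanted]
        if not train:
            raise ValueError(f"class {spec.name!r}: train override matches no member")
        return TrainingPartition(train=train, test=test)
    return partition_class(members, k=k)


def run_pipeline(config: RunConfig, class_specs: list[ClassSpec]) -> PipelineResult:
    """Derive every class, build the ontology, infer the hierarchy, classify
    the held-out test members, and score them against their source classes."""
    if not class_specs:
        raise ValueError("empty class list")
    names = [s.name for s in class_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")

    library = (
        load_pattern_library(config.pattern_library) if config.use_library else None
    )
    frag_spec = FragmentationSpec(max_cuts=config.max_cuts)

    partitions: dict[str, TrainingPartition] = {}
    fingerprints: dict[str, ConsensusFingerprint] = {}
    convergence: dict[str, ConvergenceReport] = {}
    for spec in class_specs:
        try:
            partitions[spec.name] = _partition(spec, config.k, config.strip_salts)
            fingerprints[spec.name] = consensus_fingerprint(
                partitions[spec.name],
                library=library,
                class_name=spec.name,
                spec=frag_spec,
                k=config.k,
            )
        except Exception as exc:
            raise ChemontogenError(f"stage 'derive' failed for class {spec.name!r}: {exc}") from exc

    if config.cross_class_screening:
        # second pass: screen each class against the union of all other
        # classes' consensus patterns (deterministic, order-independent)
        firstpass = {name: set(fp.features) for name, fp in fingerprints.items()}
        for spec in class_specs:
            others: set[CanonicalPattern] = set()
            for name, feats in firstpass.items():
                if name != spec.name:
                    others |= feats
            fingerprints[spec.name] = consensus_fingerprint(
                partitions[spec.name],
                library=library,
                cross_class=others,
                class_name=spec.name,
                spec=frag_spec,
                k=config.k,
            )

    for spec in class_specs:
        expected = _expected_pattern(spec.expected) if spec.expected else None
        convergence[spec.name] = convergence_report(
            fingerprints[spec.name], partitions[spec.name], expected
        )

    registry = FunctionalGroupRegistry(config.namespace)
    ontology = Ontology(registry=registry)
    definitions: dict[str, ClassDefinition] = {}
    for spec in class_specs:
        try:
            cd = build_class_definition(
                spec.name,
                fingerprints[spec.name],
                registry,
                cardinality_overrides=spec.cardinality_overrides,
                attribute_restrictions=spec.attribute_restrictions,
            )
        except Exception as exc:
            raise ChemontogenError(f"stage 'axiomatize' failed for class {spec.name!r}: {exc}") from exc
        definitions[spec.name] = cd
        ontology.add_class(cd)

    hierarchy = infer_hierarchy(ontology, mode=config.mode)

    report = ClassificationReport()
    gold: dict[str, tuple[str, Optional[set[str]]]] = {}
    for spec in class_specs:
        for mol in partitions[spec.name].test:
            fp = entity_fingerprint(mol, registry)
            satisfied, most_specific = classify_entity(fp, ontology, hierarchy)
            report.add(fp.entity_id, satisfied, most_specific)
            gold[fp.entity_id] = (spec.name, None)
    evaluation = evaluate(report, gold, hier=hierarchy, name_of=hierarchy.names)

    manifest = {
        "package": "chemontogen",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "classes": {
            s.name: {
                "members": [m.identifier for m in s.members],
                "train": [m.identifier for m in partitions[s.name].train],
                "test": [m.identifier for m in partitions[s.name].test],
                "n_features": len(fingerprints[s.name].features),
                "n_principal": len(fingerprints[s.name].principal),
            }
            for s in class_specs
        },
    }

    result = PipelineResult(
        ontology=ontology,
        hierarchy=hierarchy,
        fingerprints=fingerprints,
        partitions=partitions,
        convergence=convergence,
        definitions=definitions,
        report=report,
        evaluation=evaluation,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_owl(result.ontology, outdir / "classes.owl")
    (outdir / "hierarchy.json").write_text(result.hierarchy.to_json() + "\n")
    (outdir / "hierarchy.dot").write_text(result.hierarchy.to_dot() + "\n")
    manch = "\n\n".join(
        to_manchester(cd, result.ontology.registry)
        for _name, cd in sorted(result.definitions.items())
    )
    (outdir / "definitions.manchester.txt").write_text(manch + "\n")
    (outdir / "classification.json").write_text(
        json.dumps({"entries": result.report.entries, "evaluation": result.evaluation}, indent=2) + "\n"
    )
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    # isotope sidecar for the primitives appearing in registry patterns
    prims = []
    for pattern, _uri in result.ontology.registry.items():
        if pattern.kind == "smarts" and pattern.graph is not None:
            prims.extend(pattern.graph.nodes)
    if prims:
        isotope_table().write_sidecar(outdir / "isotope_table.tsv", prims)


def per_class_record(name: str, result: PipelineResult) -> dict:
    """JSON-ready record of one class's derivation (ids, features, flags)."""
    fp = result.fingerprints[name]
    part = result.partitions[name]
    conv = result.convergence[name]
    return {
        "class": name,
        "train": [m.identifier for m in part.train],
        "test": [m.identifier for m in part.test],
        "features": sorted(
            (
                {"text": p.text, "kind": p.kind, "origin": p.origin, "fraction": 1.0}
                for p in fp.features
            ),
            key=lambda d: d["text"],
        ),
        "principal": sorted(p.text for p in fp.principal),
        "convergence": {
            "empty_fingerprint": conv.empty_fingerprint,
            "only_single_atom_principals": conv.only_single_atom_principals,
            "expected": conv.expected_text,
            "expected_present": conv.expected_present,
            "non_matching_members": conv.non_matching_members,
        },
    }
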