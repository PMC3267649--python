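import re

import pytest

from chemontogen.axioms import (
    AttributeRestriction,
    FunctionalGroupRegistry,
    Ontology,
    build_class_definition,
    functional_group_uri,
    import_ontology,
    read_owl,
    to_manchester,
    write_owl,
)
from chemontogen.canonical import verbatim_pattern
from chemontogen.consensus import ConsensusFingerprint
from chemontogen.errors import MergeConflictError, UnsupportedAxiomError


def _fp(name, *texts):
    return ConsensusFingerprint(class_name=name, features={verbatim_pattern(t) for t in texts})


ALCOHOL_TEXTS = ("[#6]", "[#8]", "[#6][#8]", "[#6][OX2H]")


class TestFunctionalGroupUri:
    def test_deterministic(self):
        a = functional_group_uri(verbatim_pattern("[#6]"))
        b = functional_group_uri(verbatim_pattern("[#6]"))
        assert a == b

    def test_distinct_patterns_distinct_uris(self):
        assert functional_group_uri(verbatim_pattern("[#6]")) != functional_group_uri(
            verbatim_pattern("[#8]")
        )

    def test_shape_is_40_lowercase_hex(self):
        uri = functional_group_uri(verbatim_pattern("[#6][OX2H]"))
        suffix = uri.rsplit("/", 1)[-1]
        assert re.fullmatch(r"[0-9a-f]{40}", suffix)

    def test_registry_rebuild_identical(self):
        r1, r2 = FunctionalGroupRegistry(), FunctionalGroupRegistry()
        for t in reversed(ALCOHOL_TEXTS):
            r2.register(verbatim_pattern(t))
        for t in ALCOHOL_TEXTS:
            r1.register(verbatim_pattern(t))
        assert {u for _p, u in r1.items()} == {u for _p, u in r2.items()}


class TestBuildClassDefinition:
    def test_alcohols_four_restrictions_min_one(self):
        reg = FunctionalGroupRegistry()
        cd = build_class_definition("Organic Alcohols", _fp("alc", *ALCOHOL_TEXTS), reg)
        assert len(cd.restrictions) == 4
        assert all(r.min_count == 1 for r in cd.restrictions.values())

    def test_diols_min2_override(self):
        reg = FunctionalGroupRegistry()
        cd = build_class_definition(
            "Diols", _fp("diols", *ALCOHOL_TEXTS), reg, cardinality_overrides={"[#6][OX2H]": 2}
        )
        uri = reg.uri_for("[#6][OX2H]")
        assert cd.restrictions[uri].min_count == 2

    def test_reactive_diols_attribute(self):
        reg = FunctionalGroupRegistry()
        cd = build_class_definition(
            "Reactive Diols",
            _fp("diols", *ALCOHOL_TEXTS),
            reg,
            cardinality_overrides={"[#6][OX2H]": 2},
            attribute_restrictions=[AttributeRestriction("molecular weight", "le", hi=500.0)],
        )
        assert cd.attributes[0].accepts(400) and not cd.attributes[0].accepts(600)

    def test_override_for_unknown_pattern_rejected(self):
        reg = FunctionalGroupRegistry()
        with pytest.raises(ValueError, match="overrides"):
            build_class_definition(
                "Diols", _fp("diols", "[#6]"), reg, cardinality_overrides={"[#7]": 2}
            )


class TestManchester:
    def _diols(self, reg):
        return build_class_definition(
            "Diols", _fp("diols", *ALCOHOL_TEXTS), reg, cardinality_overrides={"[#6][OX2H]": 2}
        )

    def test_alcohols_rendering(self):
        reg = FunctionalGroupRegistry()
        cd = build_class_definition("Organic Alcohols", _fp("alc", *ALCOHOL_TEXTS), reg)
        text = to_manchester(cd, reg)
        assert "EquivalentTo" in text
        assert "'Molecular entity'" in text
        assert "'has part' some '[#6][OX2H]'" in text

    def test_diols_min_two(self):
        reg = FunctionalGroupRegistry()
        assert "min 2 '[#6][OX2H]'" in to_manchester(self._diols(reg), reg)

    def test_attribute_only_class(self):
        reg = FunctionalGroupRegistry()
        cd = build_class_definition(
            "Small Molecules",
            None,
            reg,
            attribute_restrictions=[AttributeRestriction("molecular weight", "le", hi=500.0)],
        )
        text = to_manchester(cd, reg)
        assert "has part" not in text
        assert "'has value' [= < 500.0]" in text

    def test_deterministic_order(self):
        r1, r2 = FunctionalGroupRegistry(), FunctionalGroupRegistry()
        a = to_manchester(self._diols(r1), r1)
        b = to_manchester(self._diols(r2), r2)
        assert a == b


def _fixture_ontology(families=("alcohols", "diols"), seed=5) -> Ontology:
    from chemontogen.workbench import ClassSpec, RunConfig, SeriesSpec, generate_series, run_pipeline

    specs = []
    for fam in families:
        ov = {"diols": {"[#6][OX2H]": 2}, "triols": {"[#6][OX2H]": 3}}.get(fam, {})
        specs.append(
            ClassSpec(
                name=fam,
                members=generate_series(SeriesSpec(family=fam, count=6), seed=seed),
                cardinality_overrides=ov,
            )
        )
    return run_pipeline(RunConfig(seed=seed), specs).ontology


class TestOwlRoundTrip:
    def test_round_trip_structural_equality(self, tmp_path):
        ont = _fixture_ontology()
        path = tmp_path / "classes.owl"
        write_owl(ont, path)
        assert ont.structurally_equal(read_owl(path))

    def test_functional_group_document_is_flat(self, tmp_path):
        from rdflib import Graph
        from rdflib.namespace import RDFS

        ont = _fixture_ontology()
        _cls, fg_path = write_owl(ont, tmp_path / "classes.owl")
        g = Graph()
        g.parse(str(fg_path), format="xml")
        assert len(list(g.triples((None, RDFS.subClassOf, None)))) == 0

    def test_registry_sidecar_written(self, tmp_path):
        ont = _fixture_ontology()
        write_owl(ont, tmp_path / "classes.owl")
        tsv = (tmp_path / "classes.registry.tsv").read_text().splitlines()
        assert tsv[0] == "uri\tlabel\tkind"
        assert len(tsv) - 1 == len(ont.registry)

    def test_unknown_property_rejected(self, tmp_path):
        ont = _fixture_ontology(families=("alcohols",))
        path = tmp_path / "classes.owl"
        write_owl(ont, path)
        text = path.read_text().replace("property/hasPart", "property/hasMystery")
        path.write_text(text)
        with pytest.raises(UnsupportedAxiomError):
            read_owl(path)


class TestImportOntology:
    def test_idempotent(self):
        a = _fixture_ontology(families=("alcohols",))
        merged = import_ontology(a, a)
        assert merged.structurally_equal(a)

    def test_commutative(self):
        a = _fixture_ontology(families=("alcohols",))
        b = _fixture_ontology(families=("amines",))
        assert import_ontology(a, b).structurally_equal(import_ontology(b, a))

    def test_class_count_adds_up(self):
        a = _fixture_ontology(families=("alcohols", "diols"))
        b = _fixture_ontology(families=("amines", "ethers"))
        assert len(import_ontology(a, b).classes) == 4

    def test_shared_feature_single_registry_entry(self):
        a = _fixture_ontology(families=("alcohols",))
        b = _fixture_ontology(families=("diols",))
        merged = import_ontology(a, b)
        carbons = [u for p, u in merged.registry.items() if p.text == "[#6]"]
        assert len(carbons) == 1

    def test_conflicting_definitions_rejected(self):
        def ont_with(texts):
            reg = FunctionalGroupRegistry()
            ont = Ontology(registry=reg)
            ont.add_class(build_class_definition("Alcohols", _fp("alc", *texts), reg))
            return ont

        a = ont_with(ALCOHOL_TEXTS)
        b = ont_with(ALCOHOL_TEXTS[:2])  # same name/URI, different conjunction
        with pytest.raises(MergeConflictError):
            import_ontology(a, b)
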