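import pytest

from chemontogen.axioms import (
    AttributeRestriction,
    FunctionalGroupRegistry,
    build_class_definition,
    Ontology,
)
from chemontogen.canonical import verbatim_pattern
from chemontogen.classifier import (
    ClassificationReport,
    classify_entity,
    count_distinct_matches,
    counts_from_instance_rdf,
    entity_fingerprint,
    evaluate,
    export_instance_rdf,
    summary_table,
)
from chemontogen.consensus import ConsensusFingerprint, consensus_fingerprint, partition_class
from chemontogen.fragmenter import fragment_features
from chemontogen.molgraph import parse_structure
from chemontogen.reasoner import infer_hierarchy

from conftest import oracle_count_embeddings

CARBINOL = verbatim_pattern("[#6][OX2H]")


class TestCountDistinctMatches:
    def test_glycerol_three_hydroxyls(self, mols):
        assert count_distinct_matches(mols["glycerol"], CARBINOL) == 3

    def test_ethanol_one(self, mols):
        assert count_distinct_matches(mols["ethanol"], CARBINOL) == 1

    def test_no_nitrogen(self, mols):
        assert count_distinct_matches(mols["ethanol"], verbatim_pattern("[#7]")) == 0

    def test_automorphisms_collapse(self, mols):
        ring = verbatim_pattern("[#6]1[#6][#6][#6][#6][#6]1")
        assert count_distinct_matches(mols["benzene"], ring) == 1

    def test_overlapping_occurrences_counted(self, mols):
        # the two C-O pairs of ethylene glycol share no atoms; the C-C-O
        # chains of glycerol overlap and still count separately
        assert count_distinct_matches(mols["ethylene_glycol"], verbatim_pattern("[#6][#8]")) == 2
        assert count_distinct_matches(mols["glycerol"], verbatim_pattern("[#6][#6][#8]")) >= 4

    @pytest.mark.parametrize("target", [
        "methane", "ethanol", "glycerol", "ethylene_glycol", "benzene",
        "toluene", "methyl_acetate", "methylamine", "cyclohexane",
    ])
    def test_equals_embedding_oracle(self, mols, target):
        """Distinct-occurrence counts equal brute-force embedding enumeration,
        exhaustively over fragment-derived patterns of small fixtures."""
        pool = set()
        for name in ["ethanol", "ethylene_glycol", "benzene", "methylamine"]:
            pool |= fragment_features(mols[name])
        mol = mols[target]
        for pattern in sorted(pool, key=lambda p: p.text):
            assert count_distinct_matches(mol, pattern) == oracle_count_embeddings(mol, pattern), (
                target,
                pattern.text,
            )


def _alcohol_diol_ontology():
    reg = FunctionalGroupRegistry()
    texts = ["[#6]", "[#8]", "[#6][#8]", "[#6][OX2H]"]
    fp = ConsensusFingerprint(class_name="x", features={verbatim_pattern(t) for t in texts})
    ont = Ontology(registry=reg)
    ont.add_class(build_class_definition("alcohols", fp, reg))
    ont.add_class(
        build_class_definition("diols", fp, reg, cardinality_overrides={"[#6][OX2H]": 2})
    )
    return ont, reg


class TestEntityFingerprint:
    def test_ethanol_counts(self, mols):
        ont, reg = _alcohol_diol_ontology()
        fp = entity_fingerprint(mols["ethanol"], reg)
        by_label = {reg.label_for(u): n for u, n in fp.counts.items()}
        assert by_label == {"[#6]": 2, "[#8]": 1, "[#6][#8]": 1, "[#6][OX2H]": 1}

    def test_methane_zeros_recorded(self, mols):
        _ont, reg = _alcohol_diol_ontology()
        fp = entity_fingerprint(mols["methane"], reg)
        by_label = {reg.label_for(u): n for u, n in fp.counts.items()}
        assert by_label == {"[#6]": 1, "[#8]": 0, "[#6][#8]": 0, "[#6][OX2H]": 0}

    def test_molecular_weight_always_attached(self, mols):
        _ont, reg = _alcohol_diol_ontology()
        for mol in mols.values():
            fp = entity_fingerprint(mol, reg)
            value, unit = fp.attributes["molecular weight"]
            assert value > 0 and unit == "dalton"


class TestClassifyEntity:
    def test_cardinality_separates_diols(self, mols):
        ont, reg = _alcohol_diol_ontology()
        hier = infer_hierarchy(ont)
        names = lambda uris: {ont.name_of(u) for u in uris}

        glycol = entity_fingerprint(mols["ethylene_glycol"], reg)
        sat, most = classify_entity(glycol, ont, hier)
        assert names(sat) == {"alcohols", "diols"}
        assert names(most) == {"diols"}

        ethanol = entity_fingerprint(mols["ethanol"], reg)
        sat, most = classify_entity(ethanol, ont, hier)
        assert names(sat) == names(most) == {"alcohols"}

        glycerol = entity_fingerprint(mols["glycerol"], reg)
        sat, _most = classify_entity(glycerol, ont, hier)
        assert "diols" in names(sat)

    def test_attribute_bound_excludes_heavy_entity(self, mols):
        reg = FunctionalGroupRegistry()
        fp = ConsensusFingerprint(class_name="x", features={verbatim_pattern("[#6][OX2H]")})
        ont = Ontology(registry=reg)
        ont.add_class(
            build_class_definition(
                "reactive diols",
                fp,
                reg,
                cardinality_overrides={"[#6][OX2H]": 2},
                attribute_restrictions=[AttributeRestriction("molecular weight", "le", hi=500.0)],
            )
        )
        hier = infer_hierarchy(ont)
        light = entity_fingerprint(mols["ethylene_glycol"], reg)
        heavy = entity_fingerprint(parse_structure("OC" + "C" * 38 + "CO"), reg)
        assert classify_entity(light, ont, hier)[0]
        assert not classify_entity(heavy, ont, hier)[0]

    def test_ancestor_closure(self, mols):
        ont, reg = _alcohol_diol_ontology()
        hier = infer_hierarchy(ont)
        for name in ["ethanol", "ethylene_glycol", "glycerol", "methanol"]:
            sat, _ = classify_entity(entity_fingerprint(mols[name], reg), ont, hier)
            for uri in sat:
                assert hier.strict_ancestors(uri) <= sat

    def test_raising_min_count_shrinks_membership(self, mols):
        reg = FunctionalGroupRegistry()
        fp = ConsensusFingerprint(class_name="x", features={verbatim_pattern("[#6][OX2H]")})
        entities = [mols[n] for n in ["ethanol", "ethylene_glycol", "glycerol"]]
        members = []
        for n in (1, 2, 3):
            ont = Ontology(registry=reg)
            ont.add_class(
                build_class_definition(f"c{n}", fp, reg, cardinality_overrides={"[#6][OX2H]": n})
            )
            hier = infer_hierarchy(ont)
            members.append(
                {
                    e.identifier
                    for e in entities
                    if classify_entity(entity_fingerprint(e, reg), ont, hier)[0]
                }
            )
        assert members[0] >= members[1] >= members[2]

    def test_training_members_self_classify(self, alcohol_train):
        part = partition_class(alcohol_train, k=5)
        fp = consensus_fingerprint(part, class_name="alcohols")
        reg = FunctionalGroupRegistry()
        ont = Ontology(registry=reg)
        ont.add_class(build_class_definition("alcohols", fp, reg))
        hier = infer_hierarchy(ont)
        for mol in part.train:
            sat, _ = classify_entity(entity_fingerprint(mol, reg), ont, hier)
            assert sat, mol.identifier


class TestInstanceRdf:
    def test_glycerol_three_distinct_occurrences(self, mols):
        reg = FunctionalGroupRegistry()
        uri = reg.register(CARBINOL)
        fp = entity_fingerprint(mols["glycerol"], reg)
        g = export_instance_rdf(fp, reg)
        assert counts_from_instance_rdf(g, reg)[uri] == 3
        from rdflib.namespace import OWL
        from rdflib import RDF

        assert len(list(g.subjects(RDF.type, OWL.AllDifferent))) == 1

    def test_round_trip_counts(self, mols):
        _ont, reg = _alcohol_diol_ontology()
        for name in ["methane", "ethanol", "glycerol"]:
            fp = entity_fingerprint(mols[name], reg)
            recovered = counts_from_instance_rdf(export_instance_rdf(fp, reg), reg)
            assert recovered == fp.counts


class TestEvaluate:
    def _report(self, rows):
        report = ClassificationReport()
        for eid, inferred in rows:
            report.add(eid, set(inferred), set(inferred))
        return report

    def test_all_direct(self):
        report = self._report([("e1", ["alcohols"]), ("e2", ["alcohols"])])
        gold = {"e1": ("alcohols", None), "e2": ("alcohols", None)}
        s = evaluate(report, gold)
        assert s["direct_pct"] == s["correct_pct"] == 100.0

    def test_descendant_counts_correct_not_direct(self):
        ont, _reg = _alcohol_diol_ontology()
        hier = infer_hierarchy(ont)
        diols_uri = next(u for u, c in ont.classes.items() if c.name == "diols")
        report = self._report([("e1", [diols_uri])])
        s = evaluate(report, {"e1": ("alcohols", None)}, hier=hier, name_of=hier.names)
        assert s["correct"] == 1 and s["direct"] == 0

    def test_empty_report_no_division_error(self):
        s = evaluate(ClassificationReport(), {})
        assert s["total_inferences"] == 0 and s["correct_pct"] == 0.0

    def test_unknown_entity_flagged(self):
        report = self._report([("mystery", ["alcohols"])])
        s = evaluate(report, {})
        assert s["flagged_entities"] == ["mystery"]

    def test_summary_table_layout(self):
        report = self._report([("e1", ["alcohols"])])
        s = evaluate(report, {"e1": ("alcohols", None)})
        table = summary_table(s)
        assert table.splitlines()[0].startswith("Tested Category")
        assert table.splitlines()[-1].startswith("Total\t1\t1 (100.0)")
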