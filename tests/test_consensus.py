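import logging

import pytest

from chemontogen.canonical import canonical_smiles, pattern_contains, smiles_pattern
from chemontogen.consensus import (
    consensus_fingerprint,
    convergence_report,
    feature_fraction,
    mcs_closure,
    pairwise_mcs,
    partition_class,
    principal_substructures,
)
from chemontogen.fragmenter import load_pattern_library
from chemontogen.classifier import has_match
from chemontogen.molgraph import parse_structure
from chemontogen.workbench import SeriesSpec, generate_series, _expected_pattern

from conftest import oracle_mcs_size


def _mols(*smiles):
    return [parse_structure(s, identifier=s) for s in smiles]


class TestPartition:
    def test_five_smallest_in_train(self):
        members = _mols("CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC")
        part = partition_class(members, k=5)
        assert [m.identifier for m in part.train] == ["CC", "CCC", "CCCC", "CCCCC", "CCCCCC"]
        assert len(part.test) == 2
        assert max(m.complexity for m in part.train) <= min(m.complexity for m in part.test)

    def test_all_in_train_when_few(self):
        part = partition_class(_mols("C", "CC", "CCC"), k=5)
        assert len(part.train) == 3 and part.test == []

    def test_equal_size_tie_break_deterministic(self):
        a = partition_class(_mols("CCO", "CCN", "CCC"), k=2)
        b = partition_class(_mols("CCC", "CCO", "CCN"), k=2)
        assert [m.identifier for m in a.train] == [m.identifier for m in b.train]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            partition_class([])


class TestFeatureFraction:
    @pytest.mark.parametrize("smiles,expected", [
        (("CO", "CCO"), 1.0),
        (("C", "CC"), 0.0),
        (("C", "CO"), 0.5),
    ])
    def test_oxygen_fraction(self, smiles, expected):
        from chemontogen.canonical import verbatim_pattern

        assert feature_fraction(verbatim_pattern("[#8]"), _mols(*smiles)) == expected


class TestConsensusFingerprint:
    def test_alcohols_worked_example(self, alcohol_train):
        """Five small organic alcohols yield the four printed consensus
        features, with the alcohol-group pattern principal."""
        part = partition_class(alcohol_train, k=5)
        fp = consensus_fingerprint(part, class_name="Organic Alcohols")
        assert {"[#6]", "[#8]", "[#6][#8]", "[#6][OX2H]"} <= fp.feature_texts()
        assert "[#6][OX2H]" in {p.text for p in fp.principal}

    def test_disjoint_train_empty_with_warning(self, caplog):
        part = partition_class(_mols("C", "O"), k=5)
        with caplog.at_level(logging.WARNING):
            fp = consensus_fingerprint(part, class_name="nothing")
        assert fp.empty
        assert any("no consensus" in r.message for r in caplog.records)

    def test_singleton_train_keeps_all_features(self, mols):
        from chemontogen.fragmenter import fragment_features

        part = partition_class([mols["ethanol"]], k=5)
        fp = consensus_fingerprint(part)
        assert fragment_features(mols["ethanol"]) <= fp.features

    def test_adding_member_never_adds_features(self, alcohol_train):
        base = consensus_fingerprint(partition_class(alcohol_train[:3], k=5))
        more = consensus_fingerprint(partition_class(alcohol_train[:4], k=5))
        assert more.feature_texts() <= base.feature_texts()

    def test_every_feature_matches_every_train_member(self, alcohol_train):
        part = partition_class(alcohol_train, k=5)
        fp = consensus_fingerprint(part, library=load_pattern_library())
        for feature in fp.features:
            for member in part.train:
                assert has_match(member, feature), (feature.text, member.identifier)


class TestPairwiseMcs:
    def test_benzene_toluene_ring(self, mols):
        pats = pairwise_mcs([mols["benzene"], mols["toluene"]])
        assert {p.text for p in pats} == {"c1ccccc1"}

    def test_identity_pair(self, mols):
        pats = pairwise_mcs([mols["ethanol"], parse_structure("CCO")])
        assert {p.text for p in pats} == {canonical_smiles(mols["ethanol"])}

    def test_disjoint_elements_empty(self, mols):
        assert pairwise_mcs([mols["methane"], mols["water"]]) == set()

    @pytest.mark.parametrize("a,b", [
        ("c1ccccc1", "Cc1ccccc1"),
        ("CCO", "CCCO"),
        ("OCCO", "OCC(C)O"),
        ("COC(C)=O", "CC(=O)O"),
    ])
    def test_size_matches_brute_force_oracle(self, a, b):
        ma, mb = parse_structure(a), parse_structure(b)
        pats = pairwise_mcs([ma, mb])
        assert len(pats) == 1
        got = parse_structure(next(iter(pats)).text)
        assert (got.num_heavy_atoms, got.num_bonds) == oracle_mcs_size(ma, mb)

    def test_mcs_matches_both_inputs(self, mols):
        for pair in [(mols["benzene"], mols["toluene"]), (mols["ethanol"], mols["glycerol"])]:
            for pat in pairwise_mcs(list(pair)):
                assert has_match(pair[0], pat) and has_match(pair[1], pat)
                assert parse_structure(pat.text).num_heavy_atoms <= min(
                    p.num_heavy_atoms for p in pair
                )


class TestMcsClosure:
    def test_aniline_variants_recover_bare_ring(self):
        seeds = pairwise_mcs(_mols("Nc1ccccc1C", "Nc1ccccc1CC", "Nc1ccc(O)cc1"))
        closure = mcs_closure(seeds)
        assert "c1ccccc1" in {p.text for p in closure}

    def test_singleton_seed(self, mols):
        from chemontogen.fragmenter import fragment_features

        seed = smiles_pattern(mols["ethanol"].rdmol, origin="mcs")
        closure = mcs_closure({seed})
        assert seed in closure
        assert fragment_features(mols["ethanol"]) <= closure

    def test_empty_seeds(self):
        assert mcs_closure(set()) == set()


class TestPrincipal:
    def test_alcohols_principal_contains_others(self, alcohol_train):
        fp = consensus_fingerprint(partition_class(alcohol_train, k=5))
        carbinol = next(p for p in fp.principal if p.text == "[#6][OX2H]")
        others = [f for f in fp.features if f.canonicalizable and f.text != carbinol.text]
        assert any(pattern_contains(carbinol, f) for f in others)
        for f in others:
            assert not pattern_contains(f, carbinol) or f.text == carbinol.text

    def test_single_feature_is_principal(self, mols):
        pat = smiles_pattern(mols["methane"].rdmol)
        assert principal_substructures({pat}) == {pat}

    def test_peptide_backbone_principal(self):
        """A small peptide series keeps the N-C-C(=O) backbone in a principal
        substructure (glycylglycine-like chains)."""
        peptides = _mols(
            "NCC(=O)NCC(=O)O",        # Gly-Gly
            "CC(N)C(=O)NCC(=O)O",     # Ala-Gly
            "NCC(=O)NC(C)C(=O)O",     # Gly-Ala
            "CC(N)C(=O)NC(C)C(=O)O",  # Ala-Ala
            "NCC(=O)NCC(=O)NCC(=O)O", # Gly-Gly-Gly
        )
        fp = consensus_fingerprint(partition_class(peptides, k=5), class_name="peptides")
        backbone = parse_structure("NCC=O")
        principal_mols = [p for p in fp.principal if p.kind == "smiles"]
        assert any(
            has_match(parse_structure(p.text), smiles_pattern(backbone.rdmol))
            for p in principal_mols
        )


class TestConvergence:
    def _ester_sets(self):
        clean = generate_series(SeriesSpec(family="esters", count=4), seed=3)
        corrupt = generate_series(SeriesSpec(family="esters", count=4, corruption="n_linked"), seed=3)
        return clean, corrupt

    def test_clean_esters_expected_present(self):
        clean, _ = self._ester_sets()
        part = partition_class(clean, k=5)
        fp = consensus_fingerprint(part, class_name="esters")
        conv = convergence_report(fp, part, _expected_pattern("C(=O)OC"))
        assert conv.expected_present is True
        assert conv.non_matching_members == []
        assert not conv.suspicious

    def test_n_linked_member_breaks_convergence_and_is_named(self):
        _, corrupt = self._ester_sets()
        part = partition_class(corrupt, k=5)
        fp = consensus_fingerprint(part, class_name="esters")
        conv = convergence_report(fp, part, _expected_pattern("C(=O)OC"))
        assert conv.expected_present is False
        assert conv.non_matching_members == ["esters-corrupt-n_linked"]
        # the carboxyl-like carbonyl pattern survives
        assert "O=CO" in fp.feature_texts()

    def test_empty_consensus_flagged(self):
        part = partition_class(_mols("C", "O"), k=5)
        fp = consensus_fingerprint(part, class_name="nothing")
        conv = convergence_report(fp, part)
        assert conv.empty_fingerprint and conv.suspicious
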