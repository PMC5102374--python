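"""Packaged genus dataset: structure, provenance and internal consistency."""

import hashlib

import pytest

from euplotia import fixtures
from euplotia.biogeography import ConsensusTie
from euplotia.characters import validate_against_tree
from euplotia.morphokey import Interval
from euplotia.tree import mrca_clade


@pytest.fixture(scope="module")
def tree():
    return fixtures.load_species_tree()


@pytest.fixture(scope="module")
def matrix():
    return fixtures.load_characters()


@pytest.fixture(scope="module")
def clades():
    return fixtures.load_clades()


class TestSpeciesTree:
    def test_46_taxa(self, tree):
        assert len(tree.tips()) == 46

    def test_matrix_and_tree_agree(self, tree, matrix):
        assert validate_against_tree(matrix, tree).ok

    def test_every_species_in_one_clade_and_one_subclade(self, tree, clades):
        tips = tree.tip_label_set()
        clade_members = [t for members in clades["clades"].values() for t in members]
        sub_members = [t for members in clades["subclades"].values() for t in members]
        assert sorted(clade_members) == sorted(tips)
        assert sorted(sub_members) == sorted(tips)

    def test_clades_and_subclades_monophyletic(self, tree, clades):
        for group in ("clades", "subclades"):
            for name, members in clades[group].items():
                node, below = mrca_clade(tree, set(members))
                assert below == set(members), f"{group}:{name} not monophyletic"

    def test_charon_excluded(self, tree):
        assert not any("charon" in t for t in tree.tip_label_set())
        ann = fixtures.load_annotations()
        assert "Euplotes_charon" in ann["exclusions"]
        assert "AF492705" in ann["exclusions"]

    def test_curdsi_sister_to_nobilii_raikovi(self, tree):
        node, below = mrca_clade(
            tree, {"Euplotes_curdsi", "Euplotes_nobilii", "Euplotes_raikovi"}
        )
        assert below == {
            "Euplotes_curdsi", "Euplotes_nobilii", "Euplotes_raikovi",
        }

    def test_curdsi_clade_excludes_clade_a(self, tree, clades):
        _, below = mrca_clade(
            tree, {"Euplotes_curdsi", "Euplotes_nobilii", "Euplotes_raikovi"}
        )
        assert not below & set(clades["clades"]["A"])

    def test_petzi_lineage_early_branching(self, tree):
        """The petzi+sinicus pair is one of the two children of the root."""
        kids = tree.children[tree.root]
        petzi_sets = [tree.descendant_tips(k) for k in kids]
        assert {"Euplotes_petzi", "Euplotes_sinicus"} in petzi_sets


class TestCharacters:
    def test_curdsi_states_match_description(self, matrix):
        assert matrix.state_set("Euplotes_curdsi", "dargyrome_type") == frozenset(
            {"double-eurystomus"}
        )
        assert matrix.state_set("Euplotes_curdsi", "FVC_count") == frozenset({"10"})
        assert matrix.state_set("Euplotes_curdsi", "habitat") == frozenset(
            {"brackish", "marine"}
        )

    def test_dammamensis_dargyrome_unknown(self, matrix):
        assert matrix.state_set("Euplotes_dammamensis", "dargyrome_type") is None

    def test_woodruffi_annotation(self):
        notes = fixtures.load_annotations()["notes"]
        assert '"T" shaped' in notes["Euplotes_woodruffi"]

    def test_vannus_subclade_single_dargyrome(self, matrix, clades):
        for sp in clades["subclades"]["vannus"]:
            assert matrix.state_set(sp, "dargyrome_type") == frozenset({"single"})

    def test_habitat_cells_are_valid_classes(self, matrix):
        from euplotia.biogeography import HABITAT_ORDER

        for t in matrix.taxa:
            cell = matrix.state_set(t, "habitat")
            if cell:
                assert cell <= set(HABITAT_ORDER)


class TestTable1:
    def test_six_profiles(self):
        profiles = fixtures.load_table1()
        assert len(profiles) == 6
        assert {p.name for p in profiles} >= {"Euplotes_curdsi", "Euplotes_alatus"}

    def test_curdsi_azm_interval(self):
        curdsi = next(p for p in fixtures.load_table1()
                      if p.name == "Euplotes_curdsi")
        azm = curdsi.traits["AZM_membranelles"]
        assert (azm.lo, azm.hi) == (25, 34)

    def test_approx_values_expand_ten_percent(self):
        ant = next(p for p in fixtures.load_table1()
                   if p.name == "Euplotes_antarcticus")
        size = ant.traits["size_length_um"]
        assert (size.lo, size.hi) == pytest.approx((76.5, 93.5))

    def test_antarcticus_dargyrome_missing(self):
        ant = next(p for p in fixtures.load_table1()
                   if p.name == "Euplotes_antarcticus")
        assert "dargyrome_type" not in ant.traits


class TestProvenance:
    def test_every_cell_tagged(self, matrix):
        prov = fixtures.load_provenance()
        for t in matrix.taxa:
            for c in matrix.characters:
                assert (t, c.name) in prov
                assert prov[(t, c.name)] in {
                    "text", "table", "figure-transcription",
                }

    def test_summary_reports_figure_fraction(self):
        s = fixtures.provenance_summary()
        assert 0 < s["figure_transcribed_fraction"] < 1

    def test_manifest_matches_files(self):
        man = fixtures.manifest()
        assert set(man) == set(fixtures._DATA_FILES)
        for name, digest in man.items():
            data = fixtures._path(name).read_bytes()
            assert hashlib.sha256(data).hexdigest() == digest


class TestSubcladeView:
    def test_fifteen_subclade_tips(self):
        sub = fixtures.load_subclade_tree()
        assert len(sub.tips()) == 15
        assert sub.tip_label_set() == set(fixtures.load_clades()["subclades"])

    def test_habitat_consensus_values(self):
        m = fixtures.derive_subclade_matrix()
        # the freshwater radiation subclades resolve to freshwater
        assert m.state_set("patella", "habitat") == frozenset({"freshwater"})
        assert m.state_set("eurystomus", "habitat") == frozenset({"freshwater"})
        # the curdsi subclade is marine by majority despite euryhaline members
        assert m.state_set("curdsi", "habitat") == frozenset({"marine"})

    def test_tie_becomes_polymorphic_cell(self):
        res = fixtures.biogeography.subclade_consensus(["marine", "freshwater"])
        assert isinstance(res, ConsensusTie)

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError, match="unknown fixture"):
            fixtures.load_fixture("no_such_thing")
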