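"""Parsimony machinery against the exhaustive oracle and worked cases."""

import numpy as np
import pytest

from euplotia.characters import CharacterDef, CharacterMatrix, MatrixError
from euplotia.parsimony import (
    count_independent_origins,
    count_min_changes,
    count_transitions,
    enumerate_mprs,
    event_summary,
    hartigan_min_changes,
    reconstruct,
)
from euplotia.synthdata import SimConfig, evolve_character, simulate_yule, tip_matrix
from euplotia.tree import parse_newick

from conftest import (
    binary_matrix,
    oracle_enumerate,
    oracle_origin_interval,
    random_instance,
)


class TestWorkedCases:
    def test_uniform_character_no_change(self):
        tree = parse_newick("((A,B),(C,D));")
        m = binary_matrix({t: "0" for t in "ABCD"})
        rec = reconstruct(tree, m, "trait")
        assert rec.min_changes == 0
        assert all(s == frozenset({"0"}) for s in rec.node_state_sets.values())
        assert len(enumerate_mprs(tree, m, "trait").assignments) == 1

    def test_quartet_two_mprs(self, quartet):
        tree, m = quartet
        rec = reconstruct(tree, m, "trait")
        assert rec.min_changes == 1
        assert rec.root_states == frozenset({"0", "1"})
        mprs = enumerate_mprs(tree, m, "trait")
        assert len(mprs.assignments) == 2 and not mprs.truncated

    def test_quartet_transition_interval(self, quartet):
        tree, m = quartet
        assert count_transitions(tree, m, "trait", "0", "1") == (0, 1)

    def test_cherry_symmetry_two_mprs(self):
        tree = parse_newick("(A,B);")
        m = binary_matrix({"A": "0", "B": "1"})
        assert len(enumerate_mprs(tree, m, "trait").assignments) == 2

    def test_no_tip_with_state_no_origin(self):
        tree = parse_newick("((A,B),(C,D));")
        m = binary_matrix({t: "0" for t in "ABCD"})
        assert count_independent_origins(tree, m, "trait", "1") == (0, 0)

    def test_two_separated_cherries_two_origins(self):
        """Two derived cherries separated along an 8-tip backbone cannot be
        merged into one origin by any MPR."""
        tree = parse_newick("((((a1,a2),x1),x2),(((b1,b2),x3),x4));")
        states = {"a1": "1", "a2": "1", "b1": "1", "b2": "1",
                  "x1": "0", "x2": "0", "x3": "0", "x4": "0"}
        m = binary_matrix(states)
        _, assignments = oracle_enumerate(tree, m, "trait")
        expected = oracle_origin_interval(tree, assignments, "1")
        got = count_independent_origins(tree, m, "trait", "1")
        assert got == expected
        assert got[0] == 2

    def test_missing_tips_are_unconstrained(self):
        tree = parse_newick("((A,B),(C,D));")
        m = binary_matrix({"A": "0", "B": None, "C": None, "D": "0"})
        rec = reconstruct(tree, m, "trait")
        assert rec.min_changes == 0
        assert rec.node_state_sets["B"] == frozenset({"0", "1"})


class TestErrors:
    def test_unknown_character(self, quartet):
        tree, m = quartet
        with pytest.raises(MatrixError, match="not found"):
            reconstruct(tree, m, "nope")

    def test_taxon_mismatch_mentions_validator(self, quartet):
        _, m = quartet
        tree = parse_newick("((A,B),(C,Z));")
        with pytest.raises(MatrixError, match="validate_against_tree"):
            reconstruct(tree, m, "trait")

    def test_limit_below_one(self, quartet):
        tree, m = quartet
        with pytest.raises(ValueError):
            enumerate_mprs(tree, m, "trait", limit=0)

    def test_truncation_flagged(self, quartet):
        tree, m = quartet
        mprs = enumerate_mprs(tree, m, "trait", limit=1)
        assert mprs.truncated and len(mprs.assignments) == 1

    def test_unknown_state_in_transition_query(self, quartet):
        tree, m = quartet
        with pytest.raises(MatrixError):
            count_transitions(tree, m, "trait", "0", "9")


class TestSankoffCustomCosts:
    def test_asymmetric_costs_change_optimum(self):
        # loss (1 -> 0) cheap, gain (0 -> 1) expensive: a 0,1,1,1 quartet
        # roots at 1 with two independent statements of the same cost
        tree = parse_newick("((A,B),(C,D));")
        cd = CharacterDef(
            name="trait", states=("0", "1"),
            costs=np.array([[0.0, 10.0], [1.0, 0.0]]),
        )
        cells = {(t, "trait"): frozenset([s])
                 for t, s in zip("ABCD", "0111")}
        m = CharacterMatrix(taxa=list("ABCD"), characters=[cd], cells=cells)
        rec = reconstruct(tree, m, "trait")
        assert rec.root_states == frozenset({"1"})
        assert rec.min_changes == 1.0

    def test_unit_cost_matrix_matches_fitch(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tree, m = random_instance(rng)
            unit = CharacterDef(
                name="trait",
                states=m.characters[0].states,
                costs=1.0 - np.eye(len(m.characters[0].states)),
            )
            m_unit = CharacterMatrix(taxa=m.taxa, characters=[unit],
                                     cells=dict(m.cells))
            sankoff = count_min_changes(tree, m_unit, "trait")
            assert sankoff == hartigan_min_changes(tree, m, "trait")


class TestProperties:
    def test_monotonicity_adding_a_tip(self):
        """Grafting a new tip onto a random edge never lowers min changes."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            tree, m = random_instance(rng, missing_rate=0.0, poly_rate=0.0)
            before = count_min_changes(tree, m, "trait")
            # graft: pick a tip, replace it by a cherry (old tip, new tip)
            victim = sorted(tree.tip_label_set())[
                int(rng.integers(len(tree.tip_label_set())))
            ]
            newick = (
                tree_to_newick_with_graft(tree, victim, "NEWTIP")
            )
            grafted = parse_newick(newick)
            states = {t: next(iter(m.state_set(t, "trait")))
                      for t in m.taxa}
            states["NEWTIP"] = str(rng.integers(len(m.characters[0].states)))
            m2 = binary_matrix(states, space=m.characters[0].states)
            after = count_min_changes(grafted, m2, "trait")
            assert after >= before

    def test_simulated_history_bounds_parsimony(self):
        """True event counts always dominate the parsimony minimum."""
        rng = np.random.default_rng(23)
        for _ in range(200):
            tree = simulate_yule(SimConfig(n_tips=int(rng.integers(4, 20)),
                                           seed=int(rng.integers(2**31))))
            hist = evolve_character(tree, ("0", "1", "2"),
                                    change_probability=float(rng.uniform(0, 0.5)),
                                    seed=int(rng.integers(2**31)))
            m = tip_matrix(hist)
            assert count_min_changes(tree, m, "sim") <= hist.n_events

    def test_transition_counts_sum_to_min_changes(self):
        """In every MPR under unit costs, total changes equal the minimum."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            tree, m = random_instance(rng)
            es = event_summary(tree, m, "trait")
            mc = count_min_changes(tree, m, "trait")
            assert es.total_changes == mc
            # per-MPR totals: reconstruct from enumeration
            for asg in enumerate_mprs(tree, m, "trait").assignments:
                parent = tree.parent_map()
                total = sum(
                    1 for c in parent if asg[parent[c]] != asg[c]
                )
                assert total == mc


def tree_to_newick_with_graft(tree, victim_label, new_label):
    """Serialize, replacing one tip by a cherry of (tip, new tip)."""
    from euplotia.tree import write_newick

    newick = write_newick(tree)
    assert victim_label in newick
    return newick.replace(victim_label, f"({victim_label},{new_label})", 1)
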