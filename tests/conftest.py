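"""Shared fixtures: small trees, random instances, and the exhaustive oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from euplotia.characters import CharacterDef, CharacterMatrix
from euplotia.synthdata import SimConfig, simulate_yule
from euplotia.tree import PhyloTree, parse_newick


@pytest.fixture
def quartet():
    """((A,B),(C,D)); with states 0,0,1,1 — the classic two-MPR case."""
    tree = parse_newick("((A,B),(C,D));")
    matrix = binary_matrix({"A": "0", "B": "0", "C": "1", "D": "1"})
    return tree, matrix


def binary_matrix(states: dict, name: str = "trait",
                  space: tuple = ("0", "1")) -> CharacterMatrix:
    cd = CharacterDef(name=name, states=space)
    taxa = sorted(states)
    cells = {}
    for t in taxa:
        s = states[t]
        if s is None:
            continue
        cells[(t, name)] = frozenset([s] if isinstance(s, str) else s)
    return CharacterMatrix(taxa=taxa, characters=[cd], cells=cells)


def contract_random_edges(tree: PhyloTree, rng: np.random.Generator,
                          p: float = 0.3) -> PhyloTree:
    """Collapse random internal edges to create polytomies."""
    children = {k: list(v) for k, v in tree.children.items()}
    internal = [n for n in tree.preorder()
                if children[n] and n != tree.root]
    for node in internal:
        if rng.random() < p and children.get(node):
            parent = next(p_ for p_, kids in children.items() if node in kids)
            i = children[parent].index(node)
            children[parent][i:i + 1] = children[node]
            del children[node]
    out = PhyloTree(
        root=tree.root,
        children={k: tuple(v) for k, v in children.items()},
        tip_labels=dict(tree.tip_labels),
    )
    out.validate()
    return out


def random_instance(rng: np.random.Generator, max_tips: int = 8,
                    n_states: int = 3, missing_rate: float = 0.1,
                    poly_rate: float = 0.1):
    """Random small tree + one-character matrix (missing and polymorphic
    cells included) for oracle comparison."""
    n_tips = int(rng.integers(3, max_tips + 1))
    tree = simulate_yule(SimConfig(n_tips=n_tips, seed=int(rng.integers(2**31))))
    tree = contract_random_edges(tree, rng)
    space = tuple(str(i) for i in range(n_states))
    states = {}
    for tip in sorted(tree.tip_label_set()):
        u = rng.random()
        if u < missing_rate:
            states[tip] = None
        elif u < missing_rate + poly_rate and n_states >= 2:
            k = int(rng.integers(2, n_states + 1))
            states[tip] = frozenset(rng.choice(space, size=k, replace=False))
        else:
            states[tip] = str(rng.integers(n_states))
    return tree, binary_matrix(states, space=space)


# ---------------------------------------------------------------------------
# Exhaustive oracle: enumerate every full ancestral assignment.
# Independent of the Sankoff/Fitch implementation under test.
# ---------------------------------------------------------------------------

def oracle_enumerate(tree: PhyloTree, matrix: CharacterMatrix, character: str):
    """All minimum-cost assignments by brute force.

    Returns (min_cost, assignments) where each assignment maps every node
    to a state label; missing tips inherit their parent's state (zero cost
    either way under a zero-diagonal cost model), matching the package's
    convention.
    """
    cd = matrix.character(character)
    states = cd.states
    parent = tree.parent_map()
    internal = tree.internal_nodes()
    tips = tree.tips()
    fixed: dict[str, str] = {}
    choice_tips: list[tuple[str, tuple[str, ...]]] = []
    missing_tips: list[str] = []
    for t in tips:
        cell = matrix.state_set(tree.tip_labels[t], character)
        if cell is None:
            missing_tips.append(t)
        elif len(cell) == 1:
            fixed[t] = next(iter(cell))
        else:
            choice_tips.append((t, tuple(s for s in states if s in cell)))

    def edge_cost(a: str, b: str) -> float:
        return cd.cost(cd.index(a), cd.index(b))

    best = float("inf")
    best_assignments = []
    choice_nodes = internal + [t for t, _ in choice_tips]
    choice_spaces = [states] * len(internal) + [c for _, c in choice_tips]
    for combo in itertools.product(*choice_spaces):
        asg = dict(zip(choice_nodes, combo))
        asg.update(fixed)
        for t in missing_tips:
            asg[t] = asg[parent[t]]
        cost = sum(
            edge_cost(asg[parent[c]], asg[c])
            for c in parent
        )
        if cost < best - 1e-9:
            best = cost
            best_assignments = [asg]
        elif abs(cost - best) <= 1e-9:
            best_assignments.append(asg)
    return best, best_assignments


def oracle_node_sets(tree, matrix, character, assignments):
    """Internal-node MPR state sets from oracle assignments; tip sets follow
    the observed/full convention."""
    cd = matrix.character(character)
    out = {}
    for n in tree.preorder():
        if tree.is_tip(n):
            cell = matrix.state_set(tree.tip_labels[n], character)
            out[n] = frozenset(cd.states) if cell is None else frozenset(cell)
        else:
            out[n] = frozenset(a[n] for a in assignments)
    return out


def oracle_transition_interval(tree, assignments, from_state, to_state):
    parent = tree.parent_map()
    counts = [
        sum(1 for c in parent if a[parent[c]] == from_state and a[c] == to_state)
        for a in assignments
    ]
    return min(counts), max(counts)


def oracle_origin_interval(tree, assignments, state):
    parent = tree.parent_map()
    counts = []
    for a in assignments:
        n = sum(
            1
            for node, s in a.items()
            if s == state and (node not in parent or a[parent[node]] != state)
        )
        counts.append(n)
    return min(counts), max(counts)
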