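"""Parsimony ancestral-state reconstruction and event counting.

The minimum-change criterion is evaluated with Sankoff dynamic programming
(arbitrary non-negative cost matrices, polytomies handled natively by
summing over all children) and cross-checked, under unit costs, against a
Hartigan-style generalization of the Fitch set algorithm. Most-parsimonious
reconstructions (MPRs) are enumerated by deterministic backtracking over
the DP tables, which yields exact [min, max] intervals for the number of
specific transitions and of independent origins of a state across all MPRs
— the quantity behind statements like "five or six independent
occurrences".

Conventions:

* the tree is used as rooted, with no prior on the root state (the optimum
  is the minimum over root assignments);
* a missing tip ("?") constrains nothing: it costs zero for every state,
  and in every enumerated MPR it simply inherits its parent's state, so it
  never contributes transitions or independent origins;
* a polymorphic tip behaves exactly as a tip whose allowed state set is the
  given set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .characters import CharacterDef, CharacterMatrix, MatrixError
from .tree import PhyloTree

__all__ = [
    "Reconstruction",
    "EventSummary",
    "reconstruct",
    "count_min_changes",
    "enumerate_mprs",
    "count_transitions",
    "count_independent_origins",
    "event_summary",
]

_EPS = 1e-9


@dataclass
class Reconstruction:
    """Per-node optimal state sets for one character on one tree.

    ``node_state_sets`` holds, for every internal node, exactly the states
    that appear at that node in at least one MPR; at tips it holds the
    observed state set (or the full state space when the tip is missing).
    """

    character: CharacterDef
    min_changes: float
    node_state_sets: dict[str, frozenset]
    root_states: frozenset


@dataclass
class EventSummary:
    """Transition and origin counts over all MPRs for one character."""

    character: CharacterDef
    total_changes: float
    per_transition: dict[tuple[str, str], tuple[int, int]]
    origins: dict[str, tuple[int, int]]
    n_mprs: int
    complete: bool = True


class _Engine:
    """Shared DP state for one (tree, matrix, character) problem."""

    def __init__(self, tree: PhyloTree, matrix: CharacterMatrix, character: str):
        self.tree = tree
        self.char = matrix.character(character)
        self.k = len(self.char.states)
        missing_taxa = sorted(tree.tip_label_set() - set(matrix.taxa))
        if missing_taxa:
            raise MatrixError(
                f"tree tips absent from matrix: {missing_taxa}; "
                "run validate_against_tree for a full report"
            )
        self.parent = tree.parent_map()
        self.postorder = list(tree.postorder())
        self.preorder = list(tree.preorder())
        # allowed state indices per tip; None = missing (any state, zero cost)
        self.allowed: dict[str, Optional[frozenset]] = {}
        for tip in tree.tips():
            cell = matrix.state_set(tree.tip_labels[tip], character)
            self.allowed[tip] = (
                None if cell is None else frozenset(self.char.index(s) for s in cell)
            )
        self._run_up()

    def cost(self, i: int, j: int) -> float:
        return self.char.cost(i, j)

    def _run_up(self) -> None:
        k, tree = self.k, self.tree
        up: dict[str, list[float]] = {}
        # edge_min[c][t]: min over child states s of cost(t, s) + up[c][s]
        edge_min: dict[str, list[float]] = {}
        for node in self.postorder:
            if tree.is_tip(node):
                a = self.allowed[node]
                up[node] = [
                    0.0 if (a is None or s in a) else math.inf for s in range(k)
                ]
            else:
                up[node] = [0.0] * k
                for c in tree.children[node]:
                    em = [
                        min(self.cost(t, s) + up[c][s] for s in range(k))
                        for t in range(k)
                    ]
                    edge_min[c] = em
                    for t in range(k):
                        up[node][t] += em[t]
        self.up = up
        self.edge_min = edge_min
        self.min_changes = min(up[self.tree.root])

    def run_down(self) -> dict[str, list[float]]:
        """Cost of the rest of the tree given each node takes each state."""
        k, tree = self.k, self.tree
        down: dict[str, list[float]] = {tree.root: [0.0] * k}
        for node in self.preorder:
            if tree.is_tip(node):
                continue
            for c in tree.children[node]:
                dc = [math.inf] * k
                for t in range(k):
                    base = down[node][t] + self.up[node][t] - self.edge_min[c][t]
                    if not math.isfinite(base):
                        continue
                    for s in range(k):
                        v = base + self.cost(t, s)
                        if v < dc[s]:
                            dc[s] = v
                down[c] = dc
        return down

    def node_state_sets(self) -> dict[str, frozenset]:
        down = self.run_down()
        states = self.char.states
        out: dict[str, frozenset] = {}
        for node in self.preorder:
            if self.tree.is_tip(node):
                a = self.allowed[node]
                idx = range(self.k) if a is None else sorted(a)
                out[node] = frozenset(states[s] for s in idx)
            else:
                out[node] = frozenset(
                    states[s]
                    for s in range(self.k)
                    if self.up[node][s] + down[node][s] <= self.min_changes + _EPS
                )
        return out

    # -- MPR enumeration ---------------------------------------------------

    def _child_choices(self, child: str, t: int) -> list[int]:
        """States of ``child`` optimal given parent state ``t`` (lexicographic)."""
        target = self.edge_min[child][t]
        return [
            s
            for s in range(self.k)
            if self.cost(t, s) + self.up[child][s] <= target + _EPS
        ]

    def iter_mprs(self) -> Iterator[dict[str, int]]:
        """All MPRs in deterministic lexicographic order of state indices.

        Missing tips are pinned to their parent's state whenever that is
        cost-optimal (it always is with a zero-diagonal cost matrix), so
        they do not multiply the MPR set.
        """
        root = self.tree.root
        root_choices = [
            s
            for s in range(self.k)
            if self.up[root][s] <= self.min_changes + _EPS
        ]
        assignment: dict[str, int] = {}
        order = self.preorder

        def assign(i: int) -> Iterator[dict[str, int]]:
            if i == len(order):
                yield dict(assignment)
                return
            node = order[i]
            if node == root:
                choices = root_choices
            else:
                t = assignment[self.parent[node]]
                if self.tree.is_tip(node) and self.allowed[node] is None:
                    # missing tip: inherit parent state if zero-cost
                    choices = [t] if self.cost(t, t) == 0 else self._child_choices(node, t)
                else:
                    choices = self._child_choices(node, t)
            for s in choices:
                assignment[node] = s
                yield from assign(i + 1)
            assignment.pop(node, None)

        yield from assign(0)


def _engine(tree, matrix, character) -> _Engine:
    return _Engine(tree, matrix, character)


def hartigan_min_changes(tree: PhyloTree, matrix: CharacterMatrix, character: str) -> int:
    """Generalized Fitch (Hartigan) change count for the unit-cost model.

    At each internal node the preliminary set is the set of states carried
    by the largest number of children; the count increases by (number of
    children minus that multiplicity). On bifurcating trees this is exactly
    the Fitch intersection/union rule.
    """
    cd = matrix.character(character)
    if cd.costs is not None:
        raise ValueError("hartigan_min_changes requires the unordered (unit) model")
    k = len(cd.states)
    full = frozenset(range(k))
    sets: dict[str, frozenset] = {}
    changes = 0
    for node in tree.postorder():
        if tree.is_tip(node):
            cell = matrix.state_set(tree.tip_labels[node], character)
            sets[node] = (
                full if cell is None else frozenset(cd.index(s) for s in cell)
            )
        else:
            counts = [0] * k
            for c in tree.children[node]:
                for s in sets[c]:
                    counts[s] += 1
            best = max(counts)
            sets[node] = frozenset(s for s in range(k) if counts[s] == best)
            changes += len(tree.children[node]) - best
    return changes


def reconstruct(tree: PhyloTree, matrix: CharacterMatrix, character: str) -> Reconstruction:
    """Sankoff reconstruction: minimum cost and per-node MPR state sets."""
    eng = _engine(tree, matrix, character)
    sets = eng.node_state_sets()
    mc = eng.min_changes
    if eng.char.costs is None:
        mc = int(round(mc))
    return Reconstruction(
        character=eng.char,
        min_changes=mc,
        node_state_sets=sets,
        root_states=sets[tree.root],
    )


def count_min_changes(tree: PhyloTree, matrix: CharacterMatrix, character: str):
    """Minimum number (or cost) of changes; Sankoff, cross-checked vs Hartigan."""
    eng = _engine(tree, matrix, character)
    if eng.char.costs is None:
        sankoff = int(round(eng.min_changes))
        fitch = hartigan_min_changes(tree, matrix, character)
        if sankoff != fitch:  # pragma: no cover - internal consistency guard
            raise AssertionError(
                f"Sankoff ({sankoff}) and Hartigan ({fitch}) disagree on "
                f"character {character!r}"
            )
        return sankoff
    return eng.min_changes


@dataclass
class MPRSet:
    """Enumerated most-parsimonious reconstructions (state labels per node)."""

    assignments: list[dict[str, str]]
    truncated: bool
    min_changes: float


def enumerate_mprs(
    tree: PhyloTree, matrix: CharacterMatrix, character: str, limit: int = 10_000
) -> MPRSet:
    """Enumerate full ancestral assignments achieving the minimum cost.

    Yields at most ``limit`` assignments; ``truncated`` flags an incomplete
    enumeration. Order is deterministic (lexicographic in the character's
    state order along a fixed preorder).
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    eng = _engine(tree, matrix, character)
    states = eng.char.states
    assignments = []
    truncated = False
    for i, mpr in enumerate(eng.iter_mprs()):
        if i >= limit:
            truncated = True
            break
        assignments.append({n: states[s] for n, s in mpr.items()})
    return MPRSet(assignments=assignments, truncated=truncated, min_changes=eng.min_changes)


def _transitions_in(tree: PhyloTree, assignment: dict[str, str]):
    for parent in tree.children:
        for child in tree.children[parent]:
            yield assignment[parent], assignment[child]


def _origins_in(tree: PhyloTree, assignment: dict[str, str], state: str) -> int:
    parent = tree.parent_map()
    n = 0
    for node, s in assignment.items():
        if s != state:
            continue
        p = parent.get(node)
        if p is None or assignment[p] != state:
            n += 1
    return n


def count_transitions(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    character: str,
    from_state: str,
    to_state: str,
    limit: int = 10_000,
) -> tuple[int, int]:
    """[min, max] count of parent->child changes ``from_state -> to_state``
    over all MPRs."""
    cd = matrix.character(character)
    cd.index(from_state), cd.index(to_state)
    mprs = enumerate_mprs(tree, matrix, character, limit=limit)
    counts = [
        sum(1 for a, b in _transitions_in(tree, asg) if a == from_state and b == to_state)
        for asg in mprs.assignments
    ]
    return (min(counts), max(counts))


def count_independent_origins(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    character: str,
    state: str,
    limit: int = 10_000,
) -> tuple[int, int]:
    """[min, max] number of independent origins of ``state`` over all MPRs.

    An origin is a maximal connected set of nodes assigned ``state`` whose
    parent (or the absence of one, at the root) does not carry it.
    """
    cd = matrix.character(character)
    cd.index(state)
    mprs = enumerate_mprs(tree, matrix, character, limit=limit)
    counts = [_origins_in(tree, asg, state) for asg in mprs.assignments]
    return (min(counts), max(counts))


def event_summary(
    tree: PhyloTree, matrix: CharacterMatrix, character: str, limit: int = 10_000
) -> EventSummary:
    """Intervals over all MPRs for every transition pair and every state's
    independent origins, plus the total minimum change count."""
    cd = matrix.character(character)
    mprs = enumerate_mprs(tree, matrix, character, limit=limit)
    pair_counts: dict[tuple[str, str], list[int]] = {
        (a, b): [] for a in cd.states for b in cd.states if a != b
    }
    origin_counts: dict[str, list[int]] = {s: [] for s in cd.states}
    for asg in mprs.assignments:
        seen: dict[tuple[str, str], int] = {}
        for a, b in _transitions_in(tree, asg):
            if a != b:
                seen[(a, b)] = seen.get((a, b), 0) + 1
        for pair, lst in pair_counts.items():
            lst.append(seen.get(pair, 0))
        for s in cd.states:
            origin_counts[s].append(_origins_in(tree, asg, s))
    mc = mprs.min_changes
    if cd.costs is None:
        mc = int(round(mc))
    return EventSummary(
        character=cd,
        total_changes=mc,
        per_transition={p: (min(v), max(v)) for p, v in pair_counts.items()},
        origins={s: (min(v), max(v)) for s, v in origin_counts.items()},
        n_mprs=len(mprs.assignments),
        complete=not mprs.truncated,
    )
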