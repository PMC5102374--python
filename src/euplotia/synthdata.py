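"""Seeded generators: Yule trees, Markov character histories, specimens.

Every generator is a pure function of its configuration and seed — the
same seed gives byte-identical output. Replicate seeds are derived from a
master seed by fixed arithmetic (``(master * 1000003 + index) mod 2^31``)
so a replicate can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .characters import CharacterDef, CharacterMatrix
from .morphokey import Interval, SpeciesProfile, Specimen, States
from .tree import PhyloTree

__all__ = [
    "SimConfig",
    "derive_seed",
    "simulate_yule",
    "evolve_character",
    "tip_matrix",
    "simulate_specimen",
]


def derive_seed(master: int, index: int) -> int:
    """Deterministic per-replicate seed (fixed arithmetic, < 2^31)."""
    return (int(master) * 1_000_003 + int(index)) % (2**31)


@dataclass
class SimConfig:
    """Parameters for tree + character simulation.

    ``change_probability`` is the per-edge probability that the state
    switches (to a uniformly chosen different state) along that edge.
    """

    n_tips: int = 16
    birth_rate: float = 1.0
    states: tuple[str, ...] = ("0", "1")
    change_probability: float = 0.1
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not (0 <= self.change_probability <= 1):
            raise ValueError("change_probability must be in [0, 1]")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")


def simulate_yule(config: SimConfig) -> PhyloTree:
    """Sample a binary rooted Yule tree with labeled tips ``t1..tn``.

    Standard forward construction: starting from a two-tip cherry, a
    uniformly chosen extant lineage splits at each step; waiting times are
    exponential with rate (birth_rate x number of lineages) and accumulate
    into branch lengths.
    """
    rng = np.random.default_rng(config.seed)
    children: dict[str, tuple[str, ...]] = {}
    lengths: dict[str, float] = {}
    counter = 0

    def new_node() -> str:
        nonlocal counter
        counter += 1
        return f"_s{counter}"

    root = new_node()
    first, second = new_node(), new_node()
    children[root] = (first, second)
    children[first] = ()
    children[second] = ()
    pending = {first: 0.0, second: 0.0}  # time since lineage began

    while len(pending) < config.n_tips:
        k = len(pending)
        wait = rng.exponential(1.0 / (config.birth_rate * k))
        for tip in pending:
            pending[tip] += wait
        tips_sorted = sorted(pending)
        chosen = tips_sorted[rng.integers(0, k)]
        a, b = new_node(), new_node()
        children[chosen] = (a, b)
        children[a] = ()
        children[b] = ()
        lengths[chosen] = pending.pop(chosen)
        pending[a] = 0.0
        pending[b] = 0.0
    # final stretch so the tree is ultrametric
    k = len(pending)
    wait = rng.exponential(1.0 / (config.birth_rate * k))
    for tip in pending:
        lengths[tip] = pending[tip] + wait

    tip_labels = {}
    i = 0
    order = [n for n in _preorder(children, root) if not children[n]]
    for node in order:
        i += 1
        tip_labels[node] = f"t{i}"
    tree = PhyloTree(
        root=root,
        children=children,
        tip_labels=tip_labels,
        branch_lengths=lengths,
    )
    tree.validate()
    return tree


def _preorder(children, root):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(children[n]))


@dataclass
class CharacterHistory:
    """Observable tip states plus the latent true history."""

    character: CharacterDef
    root_state: str
    tip_states: dict[str, str]  # tip label -> state
    events: list[tuple[str, str, str]]  # (child node id, from, to)
    node_states: dict[str, str]

    @property
    def n_events(self) -> int:
        return len(self.events)


def evolve_character(
    tree: PhyloTree,
    states: Sequence[str],
    change_probability: float,
    seed: int,
    root_state: Optional[str] = None,
) -> CharacterHistory:
    """Evolve a categorical character down the tree, recording every event.

    Along each edge, with probability ``change_probability`` the state
    switches to a uniformly chosen *different* state. The returned true
    event count is an upper bound for the parsimony minimum on the same
    tip data, since the true history is itself a valid ancestral
    assignment.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    states = tuple(states)
    if root_state is None:
        root_state = states[rng.integers(0, len(states))]
    node_states = {tree.root: root_state}
    events: list[tuple[str, str, str]] = []
    for node in tree.preorder():
        if node == tree.root:
            continue
        parent_state = node_states[_parent(tree, node)]
        if rng.random() < change_probability:
            others = [s for s in states if s != parent_state]
            new = others[rng.integers(0, len(others))]
            events.append((node, parent_state, new))
            node_states[node] = new
        else:
            node_states[node] = parent_state
    tip_states = {
        tree.tip_labels[t]: node_states[t] for t in tree.tips()
    }
    cd = CharacterDef(name="sim", states=states)
    return CharacterHistory(
        character=cd,
        root_state=root_state,
        tip_states=tip_states,
        events=events,
        node_states=node_states,
    )


def _parent(tree: PhyloTree, node: str) -> str:
    # cached per tree instance
    cache = getattr(tree, "_parent_cache", None)
    if cache is None:
        cache = tree.parent_map()
        tree._parent_cache = cache
    return cache[node]


def tip_matrix(history: CharacterHistory, name: str = "sim") -> CharacterMatrix:
    """Wrap a simulated history's tip states as a one-character matrix."""
    cd = CharacterDef(name=name, states=history.character.states)
    taxa = sorted(history.tip_states)
    cells = {
        (t, name): frozenset([history.tip_states[t]]) for t in taxa
    }
    return CharacterMatrix(taxa=taxa, characters=[cd], cells=cells)


def simulate_specimen(
    profile: SpeciesProfile, noise: float = 0.0, seed: int = 0
) -> Specimen:
    """Draw a specimen from a species profile.

    Numeric traits are drawn uniformly inside the profile interval, then
    jittered with Gaussian noise of relative standard deviation ``noise``
    (clipped at zero). Categorical traits take a seeded uniform choice
    from the profile's state set — emulating a single measured cell.
    """
    if not any(isinstance(t, Interval) for t in profile.traits.values()):
        raise ValueError("profile has no numeric trait")
    rng = np.random.default_rng(seed)
    values: dict[str, object] = {}
    for trait in sorted(profile.traits):
        t = profile.traits[trait]
        if isinstance(t, Interval):
            x = rng.uniform(t.lo, t.hi)
            if noise > 0:
                x += rng.normal(0.0, noise * abs(x))
            values[trait] = max(0.0, float(x))
        else:
            choices = sorted(t.values)
            values[trait] = choices[rng.integers(0, len(choices))]
    return Specimen(values=values)
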