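"""Salinity classes, subclade habitat consensus, and invasion counting.

Habitat bins follow the salinity classes used for *Euplotes* environments
(per-mille salinity): freshwater 0–5, brackish 5–25, marine 25–35,
hypersaline above 35. Boundaries are resolved upward — 5‰ is brackish and
25‰ is marine (the 25‰ White Sea site is a marine record) — and the bins
are total and monotone: raising salinity never moves the class down the
order freshwater < brackish < marine < hypersaline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .characters import CharacterMatrix
from .parsimony import count_independent_origins
from .tree import PhyloTree

__all__ = [
    "HABITAT_ORDER",
    "HabitatRecord",
    "ConsensusTie",
    "classify_salinity",
    "subclade_consensus",
    "count_invasions",
]

HABITAT_ORDER = ("freshwater", "brackish", "marine", "hypersaline")


def classify_salinity(salinity: float) -> str:
    """Habitat class for a salinity in per mille (‰)."""
    if salinity < 0:
        raise ValueError(f"negative salinity: {salinity}")
    if salinity < 5:
        return "freshwater"
    if salinity < 25:
        return "brackish"
    if salinity <= 35:
        return "marine"
    return "hypersaline"


@dataclass
class HabitatRecord:
    """One taxon's environmental metadata (all fields optional but taxon)."""

    taxon: str
    salinity: Optional[float] = None
    habitat: Optional[str] = None
    region: Optional[str] = None
    ecozone: Optional[str] = None

    def __post_init__(self):
        if self.habitat is not None and self.habitat not in HABITAT_ORDER:
            raise ValueError(f"unknown habitat class {self.habitat!r}")
        if self.salinity is not None:
            derived = classify_salinity(self.salinity)
            if self.habitat is None:
                self.habitat = derived
            elif self.habitat != derived:
                raise ValueError(
                    f"{self.taxon}: habitat {self.habitat!r} inconsistent with "
                    f"salinity {self.salinity}‰ ({derived})"
                )


@dataclass(frozen=True)
class ConsensusTie:
    """No strict majority: the maximal (tied) states are listed."""

    states: frozenset


def subclade_consensus(states: Iterable[str]) -> Union[str, ConsensusTie]:
    """Strict-majority consensus of habitat states within a subclade.

    ``states`` is a multiset (missing values must be excluded by the
    caller; polymorphic species contribute each of their states once). A
    state held by more than half of the values wins; otherwise the result
    is a :class:`ConsensusTie` listing the plurality states.
    """
    counts = Counter(states)
    if not counts:
        raise ValueError("no non-missing states to take a consensus of")
    total = sum(counts.values())
    best = max(counts.values())
    leaders = frozenset(s for s, c in counts.items() if c == best)
    if best * 2 > total and len(leaders) == 1:
        return next(iter(leaders))
    return ConsensusTie(states=leaders)


def count_invasions(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    state: str,
    character: str = "habitat",
    limit: int = 10_000,
) -> tuple[int, int]:
    """[min, max] independent origins of a habitat state over all MPRs.

    Thin delegate to :func:`parsimony.count_independent_origins` on the
    habitat character; an "invasion" of e.g. freshwater is one maximal
    connected freshwater region of the reconstructed tree.
    """
    return count_independent_origins(tree, matrix, character, state, limit=limit)
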