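"""Trait-range identification of *Euplotes* morphospecies.

A species profile stores, per trait, either a numeric interval (µm, counts
or % of body length) or a set of categorical states. A specimen is a set
of measured values; identification ranks candidate species by the number
of traits whose measured value falls outside the profile. Missing values —
on either side — are compatible by convention, mirroring how comparative
tables treat unreported characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

__all__ = [
    "TRAIT_SCHEMA",
    "Interval",
    "States",
    "SpeciesProfile",
    "Specimen",
    "trait_compatible",
    "identify",
    "discriminating_characters",
    "IdentificationResult",
]

#: Fixed trait schema: name -> kind ("numeric" or "categorical").
TRAIT_SCHEMA: dict[str, str] = {
    "size_length_um": "numeric",
    "shape": "categorical",
    "peristome_extent_pct": "numeric",
    "AZM_membranelles": "numeric",
    "dorsal_ridges": "categorical",
    "dargyrome_type": "categorical",
    "FVC_count": "numeric",
    "dorsolateral_kineties": "numeric",
    "middorsal_dikinetids": "numeric",
}

#: Relative half-width used to expand approximate point values ("~30
#: membranelles", "85 µm") into intervals for overlap logic.
APPROX_TOLERANCE = 0.10


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"interval min {self.lo} > max {self.hi}")

    @classmethod
    def approx(cls, value: float, tolerance: float = APPROX_TOLERANCE) -> "Interval":
        """±tolerance interval around an approximate literature value."""
        d = abs(value) * tolerance
        return cls(value - d, value + d)

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    def overlaps(self, other: "Interval") -> bool:
        # a single shared endpoint counts as overlap
        return self.lo <= other.hi and other.lo <= self.hi


@dataclass(frozen=True)
class States:
    values: frozenset

    def __init__(self, values):
        object.__setattr__(self, "values", frozenset(values))

    def contains(self, x: str) -> bool:
        return x in self.values

    def overlaps(self, other: "States") -> bool:
        return bool(self.values & other.values)


Trait = Union[Interval, States]


@dataclass
class SpeciesProfile:
    """Trait ranges for one morphospecies, with a provenance citation."""

    name: str
    traits: dict[str, Trait] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        for trait, value in self.traits.items():
            kind = TRAIT_SCHEMA.get(trait)
            if kind is None:
                raise KeyError(f"trait {trait!r} not in schema")
            if kind == "numeric" and not isinstance(value, Interval):
                raise TypeError(f"trait {trait!r} must be an Interval")
            if kind == "categorical" and not isinstance(value, States):
                raise TypeError(f"trait {trait!r} must be a States set")


@dataclass
class Specimen:
    """Measured trait values for one cell; unmeasured traits are omitted."""

    values: dict[str, Union[float, str]] = field(default_factory=dict)

    def __post_init__(self):
        for trait, v in self.values.items():
            kind = TRAIT_SCHEMA.get(trait)
            if kind is None:
                raise KeyError(f"trait {trait!r} not in schema")
            if kind == "numeric":
                if not isinstance(v, (int, float)):
                    raise TypeError(f"trait {trait!r} must be numeric")
                if v < 0:
                    raise ValueError(f"trait {trait!r} is negative: {v}")
            elif not isinstance(v, str):
                raise TypeError(f"trait {trait!r} must be a categorical state")


def trait_compatible(value, profile_trait: Optional[Trait]) -> bool:
    """Is a measured value compatible with a profile's trait range?

    Numeric values must fall inside the interval (inclusive); categorical
    states must be members of the profile set. A missing value or a missing
    profile trait is compatible by convention.
    """
    if value is None or profile_trait is None:
        return True
    return profile_trait.contains(value)


@dataclass
class IdentificationResult:
    """Ranked candidates: (species name, list of incompatible traits)."""

    ranking: list[tuple[str, list[str]]]

    @property
    def identification(self) -> Optional[str]:
        """The species name if exactly one candidate has no conflicts."""
        perfect = [name for name, bad in self.ranking if not bad]
        return perfect[0] if len(perfect) == 1 else None


def identify(specimen: Specimen, profiles: Sequence[SpeciesProfile]) -> IdentificationResult:
    """Rank profiles by number of incompatible traits (then by name)."""
    if not profiles:
        raise ValueError("no species profiles given")
    scored = []
    for p in profiles:
        bad = [
            trait
            for trait, v in sorted(specimen.values.items())
            if not trait_compatible(v, p.traits.get(trait))
        ]
        scored.append((p.name, bad))
    scored.sort(key=lambda item: (len(item[1]), item[0]))
    return IdentificationResult(ranking=scored)


def discriminating_characters(a: SpeciesProfile, b: SpeciesProfile) -> set[str]:
    """Traits whose ranges/state sets are disjoint between two profiles.

    These are the characters a comparative table would mark as
    unambiguously different. Traits missing from either profile are never
    discriminating; numeric intervals meeting at a single endpoint overlap.
    """
    out = set()
    for trait in TRAIT_SCHEMA:
        ta, tb = a.traits.get(trait), b.traits.get(trait)
        if ta is None or tb is None:
            continue
        if not ta.overlaps(tb):
            out.add(trait)
    return out
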