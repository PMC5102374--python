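"""Packaged encoding of the genus-level *Euplotes* dataset.

Ships the 46-taxon species tree (outgroup omitted), the species-level
character matrix (dargyrome type, frontoventral cirri count, habitat,
ecozone), clade/subclade membership, the six-species comparative trait
table, free-text annotations and a per-cell provenance map.

Provenance tags: ``text`` (stated in running text), ``table`` (comparative
table), ``figure-transcription`` (read off the published figures; these
cells cannot be verified against printed text and downstream claims
relying on them are treated as bounds, not equalities). The 15-subclade
synopsis tree is a computed view: it is derived from the species tree by
collapsing each subclade, and its habitat states by majority-rule
consensus — it is not an independent input.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Union

from .. import biogeography
from ..characters import CharacterDef, CharacterMatrix, read_matrix
from ..morphokey import Interval, SpeciesProfile, States
from ..tree import PhyloTree, parse_newick

__all__ = [
    "CHARACTER_DEFS",
    "load_fixture",
    "load_species_tree",
    "load_characters",
    "load_subclade_tree",
    "load_table1",
    "load_clades",
    "load_provenance",
    "load_annotations",
    "derive_subclade_matrix",
    "provenance_summary",
    "manifest",
]

_DATA_FILES = (
    "species_tree.nwk",
    "characters.tsv",
    "provenance.tsv",
    "clades.json",
    "table1.json",
    "annotations.json",
)

#: Declared state spaces (unordered unit-cost model).
CHARACTER_DEFS = [
    CharacterDef(
        name="dargyrome_type",
        states=("double-eurystomus", "double-patella", "single", "multiple", "complex"),
    ),
    CharacterDef(name="FVC_count", states=("7", "8", "9", "10")),
    CharacterDef(name="habitat", states=biogeography.HABITAT_ORDER),
    CharacterDef(name="ecozone", states=("polar", "temperate", "tropical")),
]


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def _read_text(name: str) -> str:
    return _path(name).read_text()


def load_species_tree() -> PhyloTree:
    """46-taxon species-level tree, rooted, outgroup omitted."""
    return parse_newick(_read_text("species_tree.nwk"))


def load_characters() -> CharacterMatrix:
    """Species-level matrix with declared state spaces."""
    with resources.as_file(_path("characters.tsv")) as p:
        return read_matrix(p, characters=CHARACTER_DEFS)


def load_clades() -> dict:
    return json.loads(_read_text("clades.json"))


def load_provenance() -> dict:
    """(taxon, character) -> provenance tag."""
    out: dict[tuple[str, str], str] = {}
    lines = _read_text("provenance.tsv").strip().split("\n")
    header = lines[0].split("\t")[1:]
    for line in lines[1:]:
        parts = line.split("\t")
        for char, tag in zip(header, parts[1:]):
            out[(parts[0], char)] = tag
    return out


def load_annotations() -> dict:
    return json.loads(_read_text("annotations.json"))


def _parse_trait(kind_value) -> Union[Interval, States, None]:
    if kind_value is None:
        return None
    if isinstance(kind_value, dict) and "approx" in kind_value:
        return Interval.approx(float(kind_value["approx"]))
    if isinstance(kind_value, list) and kind_value and isinstance(
        kind_value[0], (int, float)
    ):
        return Interval(float(kind_value[0]), float(kind_value[1]))
    return States(kind_value)


def load_table1() -> list[SpeciesProfile]:
    """The six comparative species profiles."""
    raw = json.loads(_read_text("table1.json"))
    profiles = []
    for p in raw["profiles"]:
        traits = {
            name: t
            for name, value in p["traits"].items()
            if (t := _parse_trait(value)) is not None
        }
        profiles.append(
            SpeciesProfile(name=p["name"], traits=traits, provenance=p["provenance"])
        )
    return profiles


def load_subclade_tree() -> PhyloTree:
    """15-tip synopsis tree: the species tree with each subclade collapsed."""
    tree = load_species_tree()
    subclades = load_clades()["subclades"]
    tip_to_sub = {
        tip: name for name, members in subclades.items() for tip in members
    }
    mrcas = {}
    for name, members in subclades.items():
        node = _mrca(tree, set(members))
        if tree.descendant_tips(node) != set(members):
            raise ValueError(f"subclade {name!r} is not monophyletic")
        mrcas[node] = name

    children: dict[str, tuple[str, ...]] = {}
    tip_labels: dict[str, str] = {}

    def build(node: str) -> str:
        if node in mrcas:
            nid = mrcas[node]
            children[nid] = ()
            tip_labels[nid] = mrcas[node]
            return nid
        children[node] = tuple(build(c) for c in tree.children[node])
        return node

    root = build(tree.root)
    sub = PhyloTree(root=root, children=children, tip_labels=tip_labels)
    sub.validate()
    return sub


def _mrca(tree: PhyloTree, tips: set) -> str:
    from ..tree import mrca_clade

    node, _ = mrca_clade(tree, tips)
    return node


def derive_subclade_matrix(consensus_characters=("habitat",)) -> CharacterMatrix:
    """Subclade-level matrix computed from the species matrix.

    Characters in ``consensus_characters`` take the strict-majority
    consensus of their member species (ties become polymorphic cells);
    all other characters take the union of member states. Missing species
    cells are excluded first; an all-missing subclade cell stays missing.
    """
    species = load_characters()
    subclades = load_clades()["subclades"]
    taxa = list(subclades)
    cells: dict[tuple[str, str], frozenset] = {}
    for cd in species.characters:
        for sub, members in subclades.items():
            pooled: list[str] = []
            for m in members:
                cell = species.state_set(m, cd.name)
                if cell:
                    pooled.extend(sorted(cell))
            if not pooled:
                continue
            if cd.name in consensus_characters:
                result = biogeography.subclade_consensus(pooled)
                states = (
                    frozenset([result])
                    if isinstance(result, str)
                    else result.states
                )
            else:
                states = frozenset(pooled)
            cells[(sub, cd.name)] = states
    return CharacterMatrix(taxa=taxa, characters=list(species.characters), cells=cells)


def provenance_summary() -> dict:
    """Share of cells per provenance tag (figure-derived fraction included)."""
    prov = load_provenance()
    counts: dict[str, int] = {}
    for tag in prov.values():
        counts[tag] = counts.get(tag, 0) + 1
    total = sum(counts.values())
    return {
        "counts": counts,
        "figure_transcribed_fraction": counts.get("figure-transcription", 0) / total,
    }


def manifest() -> dict[str, str]:
    """SHA-256 checksums of the shipped fixture files."""
    return {
        name: hashlib.sha256(_path(name).read_bytes()).hexdigest()
        for name in _DATA_FILES
    }


_LOADERS = {
    "species_tree": load_species_tree,
    "subclade_tree": load_subclade_tree,
    "characters": load_characters,
    "subclade_characters": derive_subclade_matrix,
    "table1": load_table1,
    "clades": load_clades,
    "provenance": load_provenance,
    "annotations": load_annotations,
}


def load_fixture(name: str):
    """Load a packaged fixture by name; see ``_LOADERS`` for valid names."""
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {sorted(_LOADERS)}"
        ) from None
    return loader()
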