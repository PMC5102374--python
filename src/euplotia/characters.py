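"""Character definitions, cost models and taxon-by-character matrices.

Cells hold a single state, a ``|``-separated set of states (polymorphic
taxon) or ``?`` (missing). Missing data is a first-class value: in
parsimony a missing tip allows any state at zero cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "CharacterDef",
    "CharacterMatrix",
    "MatrixError",
    "MISSING",
    "loss_only_cost_matrix",
    "merge_states",
    "read_matrix",
    "write_matrix",
    "validate_against_tree",
]

MISSING = "?"


class MatrixError(ValueError):
    """Invalid character matrix content."""


@dataclass(frozen=True)
class CharacterDef:
    """A categorical character: ordered state labels plus a cost model.

    ``costs`` is None for the unordered model (every change costs 1) or a
    square non-negative matrix with zero diagonal, indexed like ``states``.
    """

    name: str
    states: tuple[str, ...]
    costs: Optional[np.ndarray] = None

    def __post_init__(self):
        if len(self.states) < 2:
            raise MatrixError(f"character {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise MatrixError(f"character {self.name!r} has duplicate states")
        if self.costs is not None:
            c = np.asarray(self.costs, dtype=float)
            k = len(self.states)
            if c.shape != (k, k):
                raise MatrixError("cost matrix shape does not match state count")
            if (c < 0).any():
                raise MatrixError("cost matrix has negative entries")
            if np.diag(c).any():
                raise MatrixError("cost matrix diagonal must be zero")
            object.__setattr__(self, "costs", c)

    def cost(self, i: int, j: int) -> float:
        if self.costs is None:
            return 0.0 if i == j else 1.0
        return float(self.costs[i, j])

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise MatrixError(
                f"state {state!r} not in character {self.name!r} "
                f"(states: {list(self.states)})"
            ) from None


def loss_only_cost_matrix(
    states: Sequence[str], gain_penalty: float = 100.0
) -> np.ndarray:
    """Cost matrix for count-valued characters read as a story of losses.

    States must be numeric labels (e.g. cirri counts "7".."10"). Any
    decrease in count costs 1 regardless of how many units are lost (a
    single loss event may remove several cirri); any increase (a regain)
    costs ``gain_penalty``.
    """
    vals = [float(s) for s in states]
    k = len(vals)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            m[i, j] = 1.0 if vals[j] < vals[i] else float(gain_penalty)
    return m


Cell = Union[str, frozenset]


@dataclass
class CharacterMatrix:
    """Taxa x characters with categorical cells; see module docstring."""

    taxa: list[str]
    characters: list[CharacterDef]
    cells: dict[tuple[str, str], frozenset] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon labels")
        by_name = {c.name: c for c in self.characters}
        for (taxon, char), states in self.cells.items():
            cd = by_name.get(char)
            if cd is None:
                raise MatrixError(f"cell refers to unknown character {char!r}")
            for s in states:
                if s not in cd.states:
                    raise MatrixError(
                        f"taxon {taxon!r}, character {char!r}: "
                        f"state {s!r} not in declared state space"
                    )

    def character(self, name: str) -> CharacterDef:
        for c in self.characters:
            if c.name == name:
                return c
        raise MatrixError(f"character {name!r} not found")

    def state_set(self, taxon: str, character: str) -> Optional[frozenset]:
        """Allowed states for a cell; None means missing (any state)."""
        return self.cells.get((taxon, character))

    def set_cell(self, taxon: str, character: str, states) -> None:
        if states is None or states == MISSING:
            self.cells.pop((taxon, character), None)
            return
        if isinstance(states, str):
            states = [states]
        cd = self.character(character)
        for s in states:
            cd.index(s)
        self.cells[(taxon, character)] = frozenset(states)


def merge_states(
    matrix: CharacterMatrix,
    character: str,
    grouping: Mapping[str, str],
    new_name: Optional[str] = None,
) -> CharacterMatrix:
    """Return a copy of ``matrix`` with states of one character merged.

    ``grouping`` maps old state labels to new ones (unmapped states keep
    their label). Useful for coarser readings of a character, e.g.
    collapsing the two "double" dargyrome types into one state before
    asking what the root had. The merged character uses the unordered
    model regardless of the original cost matrix.
    """
    cd = matrix.character(character)
    rename = {s: grouping.get(s, s) for s in cd.states}
    new_states = tuple(dict.fromkeys(rename.values()))
    if len(new_states) < 2:
        raise MatrixError("merging would leave fewer than 2 states")
    out_name = new_name or character
    new_def = CharacterDef(name=out_name, states=new_states)
    characters = [new_def if c.name == character else c for c in matrix.characters]
    cells = {}
    for (taxon, char), states in matrix.cells.items():
        if char == character:
            cells[(taxon, out_name)] = frozenset(rename[s] for s in states)
        else:
            cells[(taxon, char)] = states
    return CharacterMatrix(taxa=list(matrix.taxa), characters=characters, cells=cells)


def _parse_cell(raw: str) -> Optional[frozenset]:
    raw = raw.strip()
    if raw == "" or raw == MISSING:
        return None
    return frozenset(part.strip() for part in raw.split("|"))


def read_matrix(
    path, characters: Optional[Sequence[CharacterDef]] = None
) -> CharacterMatrix:
    """Read a TSV matrix (first column taxon, header names characters).

    When ``characters`` is omitted, state spaces are inferred as the sorted
    set of observed states per column (unordered cost model). When given,
    every cell is validated against the declared state space and an
    unrecognized state raises :class:`MatrixError` naming taxon/character.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0].lower() not in ("taxon", "taxa", "species"):
        raise MatrixError(
            f"first column must be the taxon label, got {df.columns[0]!r}"
        )
    taxa = list(df.iloc[:, 0])
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise MatrixError(f"duplicate taxon row(s): {dup}")
    char_names = list(df.columns[1:])

    parsed: dict[tuple[str, str], Optional[frozenset]] = {}
    for _, row in df.iterrows():
        taxon = row.iloc[0]
        for name in char_names:
            parsed[(taxon, name)] = _parse_cell(row[name])

    if characters is None:
        characters = []
        for name in char_names:
            observed: set[str] = set()
            for taxon in taxa:
                cell = parsed[(taxon, name)]
                if cell:
                    observed |= cell
            characters.append(CharacterDef(name=name, states=tuple(sorted(observed))))
    else:
        characters = list(characters)
        declared = {c.name for c in characters}
        missing_defs = [n for n in char_names if n not in declared]
        if missing_defs:
            raise MatrixError(f"no CharacterDef for column(s) {missing_defs}")

    cells = {k: v for k, v in parsed.items() if v is not None}
    return CharacterMatrix(taxa=taxa, characters=characters, cells=cells)


def write_matrix(matrix: CharacterMatrix, path) -> None:
    """Write TSV in the same cell syntax read_matrix accepts."""
    rows = []
    for taxon in matrix.taxa:
        row = {"taxon": taxon}
        for c in matrix.characters:
            cell = matrix.state_set(taxon, c.name)
            if cell is None:
                row[c.name] = MISSING
            else:
                # order within the character's state list for stable output
                row[c.name] = "|".join(s for s in c.states if s in cell)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def to_nexus_characters(matrix: CharacterMatrix) -> str:
    """Minimal NEXUS-style character block export for interoperability."""
    lines = ["#NEXUS", "BEGIN CHARACTERS;"]
    lines.append(
        f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={len(matrix.characters)};"
    )
    lines.append("  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS=\"0123456789\";")
    lines.append("  CHARSTATELABELS")
    for i, c in enumerate(matrix.characters, 1):
        states = " ".join(s.replace(" ", "_") for s in c.states)
        sep = "," if i < len(matrix.characters) else ";"
        lines.append(f"    {i} {c.name} / {states}{sep}")
    lines.append("  MATRIX")
    for taxon in matrix.taxa:
        codes = []
        for c in matrix.characters:
            cell = matrix.state_set(taxon, c.name)
            if cell is None:
                codes.append("?")
            elif len(cell) == 1:
                codes.append(str(c.index(next(iter(cell)))))
            else:
                codes.append("(" + "".join(str(c.index(s)) for s in sorted(cell)) + ")")
        lines.append(f"    {taxon.replace(' ', '_')} {''.join(codes)}")
    lines.append("  ;")
    lines.append("END;")
    return "\n".join(lines) + "\n"


@dataclass
class TaxonReport:
    """Result of matrix/tree cross-validation."""

    tree_only: list[str]
    matrix_only: list[str]

    @property
    def ok(self) -> bool:
        return not self.tree_only and not self.matrix_only


def validate_against_tree(matrix: CharacterMatrix, tree: PhyloTree) -> TaxonReport:
    """Report taxa present in only one of tree/matrix; ok iff sets coincide."""
    tree_taxa = tree.tip_label_set()
    matrix_taxa = set(matrix.taxa)
    return TaxonReport(
        tree_only=sorted(tree_taxa - matrix_taxa),
        matrix_only=sorted(matrix_taxa - tree_taxa),
    )
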