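"""Rooted phylogenetic trees: parsing, writing, traversal, clade queries.

Trees are treated as rooted exactly as written; polytomies are preserved and
no automatic rerooting is performed. Internal Newick labels are interpreted
as node support when numeric, as a ``bootstrap/posterior`` pair when of the
form ``"97/1.00"``, and as a clade name otherwise.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = [
    "PhyloTree",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "mrca_clade",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Tree violates the PhyloTree invariants (e.g. duplicate tip labels)."""


_SUPPORT_PAIR = re.compile(r"^(\d+(?:\.\d+)?)/(\d+(?:\.\d+)?)$")


@dataclass
class PhyloTree:
    """A rooted tree with labeled tips, optional supports and branch lengths.

    Node ids are opaque strings; tip ids equal their (unique) tip labels.
    ``children`` maps every node id to an ordered tuple of child ids (empty
    for tips). Child order is preserved round-trip but carries no meaning:
    all comparisons in this package are order-insensitive.
    """

    root: str
    children: dict[str, tuple[str, ...]]
    tip_labels: dict[str, str] = field(default_factory=dict)
    branch_lengths: dict[str, float] = field(default_factory=dict)
    supports: dict[str, float] = field(default_factory=dict)
    posteriors: dict[str, float] = field(default_factory=dict)
    node_names: dict[str, str] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------

    def is_tip(self, node: str) -> bool:
        return not self.children[node]

    def tips(self) -> list[str]:
        return [n for n in self.preorder() if self.is_tip(n)]

    def tip_label_set(self) -> set[str]:
        return {self.tip_labels[t] for t in self.tips()}

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children[node]))

    def postorder(self) -> Iterator[str]:
        out = list(self.preorder())
        return iter(reversed(out))

    def parent_map(self) -> dict[str, str]:
        return {
            c: p for p in self.children for c in self.children[p]
        }

    def internal_nodes(self) -> list[str]:
        return [n for n in self.preorder() if not self.is_tip(n)]

    def descendant_tips(self, node: str) -> set[str]:
        """Tip labels below (and including) ``node``."""
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if self.is_tip(n):
                out.add(self.tip_labels[n])
            else:
                stack.extend(self.children[n])
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial clades as tip-label sets (order-insensitive topology key)."""
        all_tips = self.tip_label_set()
        out = set()
        for n in self.preorder():
            if n == self.root or self.is_tip(n):
                continue
            clade = frozenset(self.descendant_tips(n))
            if 1 < len(clade) < len(all_tips):
                out.add(clade)
        return out

    def validate(self) -> None:
        seen_labels: set[str] = set()
        for t in self.tips():
            lab = self.tip_labels.get(t, "")
            if not lab:
                raise TreeValidationError(f"tip {t!r} has an empty label")
            if lab in seen_labels:
                raise TreeValidationError(f"duplicate tip label {lab!r}")
            seen_labels.add(lab)
        # single root, each non-root node one parent, no cycles
        parents = self.parent_map()
        if self.root in parents:
            raise TreeValidationError("root has a parent")
        reached = set(self.preorder())
        if len(reached) != len(self.children):
            raise TreeValidationError("tree contains unreachable nodes or cycles")

    # -- export ------------------------------------------------------------

    def to_json(self) -> str:
        """Debug dump: nodes, children, annotations."""
        return json.dumps(
            {
                "root": self.root,
                "children": {k: list(v) for k, v in self.children.items()},
                "tip_labels": self.tip_labels,
                "branch_lengths": self.branch_lengths,
                "supports": self.supports,
                "posteriors": self.posteriors,
                "node_names": self.node_names,
            },
            indent=1,
            sort_keys=True,
        )


def _fresh_id(base: str, used: set[str]) -> str:
    nid = base
    while nid in used:
        nid += "_"
    used.add(nid)
    return nid


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Numeric internal labels become node supports; ``"97/1.00"`` labels are
    split into a (bootstrap, posterior) pair; other labels are kept as clade
    names. Raises :class:`NewickError` on malformed input and
    :class:`TreeValidationError` on duplicate or empty tip labels.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip label: {exc}") from exc
        raise NewickError(f"malformed Newick: {exc}") from exc

    children: dict[str, tuple[str, ...]] = {}
    tip_labels: dict[str, str] = {}
    branch_lengths: dict[str, float] = {}
    supports: dict[str, float] = {}
    posteriors: dict[str, float] = {}
    node_names: dict[str, str] = {}
    used: set[str] = set()
    counter = 0

    def build(dnode) -> str:
        nonlocal counter
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            if not label:
                raise TreeValidationError("tip with empty label")
            if label in used:
                raise TreeValidationError(f"duplicate tip label {label!r}")
            nid = _fresh_id(label, used)
            tip_labels[nid] = label
            children[nid] = ()
        else:
            counter += 1
            nid = _fresh_id(f"_n{counter}", used)
            kids = tuple(build(c) for c in dnode.child_nodes())
            children[nid] = kids
            label = dnode.label
            if label:
                m = _SUPPORT_PAIR.match(label)
                if m:
                    supports[nid] = float(m.group(1))
                    posteriors[nid] = float(m.group(2))
                else:
                    try:
                        supports[nid] = float(label)
                    except ValueError:
                        node_names[nid] = label
        if dnode.edge.length is not None:
            branch_lengths[nid] = float(dnode.edge.length)
        return nid

    root = build(dtree.seed_node)
    tree = PhyloTree(
        root=root,
        children=children,
        tip_labels=tip_labels,
        branch_lengths=branch_lengths,
        supports=supports,
        posteriors=posteriors,
        node_names=node_names,
    )
    tree.validate()
    return tree


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x)) if float(int(x)) == x and "e" not in repr(x) else repr(x)
    return repr(x)


_SAFE_LABEL = re.compile(r"^[^\s()\[\]{}:;,']+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a :class:`PhyloTree` back to Newick.

    Round-trip contract: ``parse_newick(write_newick(t))`` has the same tip
    sets per clade, the same supports/posteriors/names and branch lengths.
    """
    tree.validate()

    def render(node: str) -> str:
        if tree.is_tip(node):
            s = _quote(tree.tip_labels[node])
        else:
            inner = ",".join(render(c) for c in tree.children[node])
            if node in tree.node_names:
                label = _quote(tree.node_names[node])
            elif node in tree.posteriors:
                label = f"{_format_number(tree.supports[node])}/{tree.posteriors[node]:.2f}"
            elif node in tree.supports:
                label = _format_number(tree.supports[node])
            else:
                label = ""
            s = f"({inner}){label}"
        if node in tree.branch_lengths:
            s += f":{tree.branch_lengths[node]!r}"
        return s

    return render(tree.root) + ";"


def mrca_clade(tree: PhyloTree, tips: set[str]) -> tuple[str, set[str]]:
    """Most recent common ancestor of ``tips`` and all its descendant tips.

    Returns ``(node_id, descendant_tip_labels)``. Raises ``KeyError`` for
    unknown tip labels.
    """
    if not tips:
        raise ValueError("tip set is empty")
    known = tree.tip_label_set()
    unknown = set(tips) - known
    if unknown:
        raise KeyError(f"tip label(s) not in tree: {sorted(unknown)}")
    node = tree.root
    query = set(tips)
    while True:
        if tree.is_tip(node):
            break
        for child in tree.children[node]:
            below = tree.descendant_tips(child)
            if query <= below:
                node = child
                break
        else:
            break
    return node, tree.descendant_tips(node)
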