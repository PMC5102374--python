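"""Alignment end-trimming and pairwise identity.

The curation rule operates on an aligned nucleotide matrix: scanning
inward from each end, a column is removed while its fraction of missing
data (gaps and N) exceeds the threshold, stopping at the first compliant
column per end — interior columns are never touched, and a column with
exactly the threshold fraction (e.g. 3/5 at 0.6) is retained because the
rule is a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Union

from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "AlignmentMatrix",
    "TrimReport",
    "read_fasta_alignment",
    "trim_ends",
    "percent_identity",
]

#: Characters counted as missing data in a column.
MISSING_CHARS = frozenset("-Nn.?")

GAP_CHARS = frozenset("-.")


@dataclass
class AlignmentMatrix:
    """Ordered (label, aligned sequence) rows of equal length."""

    sequences: list[tuple[str, str]]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        labels = [l for l, _ in self.sequences]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sequence labels")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    def column(self, i: int) -> str:
        return "".join(s[i] for _, s in self.sequences)

    def missing_fraction(self, i: int) -> float:
        col = self.column(i)
        return sum(1 for c in col if c in MISSING_CHARS) / len(col)

    def to_fasta(self) -> str:
        return "".join(f">{l}\n{s}\n" for l, s in self.sequences)


def read_fasta_alignment(source) -> AlignmentMatrix:
    """Read an aligned FASTA file (path or handle)."""
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ValueError("no sequences in FASTA input")
    return AlignmentMatrix([(r.id, str(r.seq)) for r in records])


@dataclass
class TrimReport:
    removed_left: list[int] = field(default_factory=list)
    removed_right: list[int] = field(default_factory=list)
    threshold: float = 0.6

    @property
    def removed(self) -> list[int]:
        return self.removed_left + self.removed_right


def trim_ends(
    aln: AlignmentMatrix, max_missing_fraction: float = 0.6
) -> tuple[AlignmentMatrix, TrimReport]:
    """Remove end columns whose missing fraction strictly exceeds the threshold.

    Returns the trimmed alignment and a report of removed column indices
    (0-based, in the input coordinate system). Idempotent: trimming a
    trimmed alignment removes nothing.
    """
    if not (0 < max_missing_fraction < 1):
        raise ValueError("max_missing_fraction must be in (0, 1)")
    n = aln.length
    left = 0
    while left < n and aln.missing_fraction(left) > max_missing_fraction:
        left += 1
    right = n
    while right > left and aln.missing_fraction(right - 1) > max_missing_fraction:
        right -= 1
    report = TrimReport(
        removed_left=list(range(0, left)),
        removed_right=list(range(right, n)),
        threshold=max_missing_fraction,
    )
    if left == 0 and right == n:
        return aln, report
    if left >= right:
        raise ValueError("trimming removed every column of the alignment")
    trimmed = AlignmentMatrix(
        [(label, seq[left:right]) for label, seq in aln.sequences]
    )
    return trimmed, report


def _identity_over_columns(a: str, b: str) -> tuple[int, int]:
    """(identical, compared) over aligned columns, skipping gap-gap columns."""
    ident = compared = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS and y in GAP_CHARS:
            continue
        compared += 1
        if x.upper() == y.upper() and x not in GAP_CHARS:
            ident += 1
    return ident, compared


def percent_identity(a: str, b: str, mode: str = "blast-like-local") -> float:
    """Pairwise percent identity of two nucleotide sequences.

    ``global-aligned``: the inputs are rows of the same alignment
    (equal length); identity = identical columns / compared columns x 100,
    with gap-gap columns excluded.

    ``blast-like-local``: the inputs are unaligned; a local alignment
    (match +2, mismatch -3, gap open -5, gap extend -2 — BLASTn-like
    scoring) is computed and identity is taken over its columns. Reported
    values are comparable to, but not guaranteed identical with, a given
    BLAST version's output.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if mode == "global-aligned":
        if len(a) != len(b):
            raise ValueError("global-aligned mode requires equal-length rows")
        ident, compared = _identity_over_columns(a, b)
    elif mode == "blast-like-local":
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        alignment = aligner.align(a.upper().replace("U", "T"),
                                  b.upper().replace("U", "T"))[0]
        sa, sb = str(alignment[0]), str(alignment[1])
        ident, compared = _identity_over_columns(sa, sb)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if compared == 0:
        raise ValueError("no comparable columns")
    return 100.0 * ident / compared
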