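"""Alignment I/O and column bookkeeping.

The conservation analysis works over three alignments: one per subfamily and
a combined alignment of both subfamilies' domain sequences. Because the
combined alignment is built independently, its columns do not line up with
the subfamily alignments by index; ``build_column_map`` recovers the
correspondence through the sequences the alignments share, and
``column_to_reference`` translates a column into a residue number on a
reference (structure) sequence so classified columns can be reported in
structure numbering (e.g. "Asp-266").

Columns are 1-based throughout.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from typing import TextIO

from Bio import SeqIO


@dataclass(frozen=True)
class ResidueRef:
    """A residue of a reference sequence, in reference numbering."""

    seq_id: str
    number: int
    amino_acid: str


class Alignment:
    """A validated multiple sequence alignment (rows of equal length)."""

    def __init__(self, rows: list[tuple[str, str]]):
        if len(rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for _, s in rows}
        if len(lengths) != 1:
            bad = [sid for sid, s in rows if len(s) != len(rows[0][1])]
            raise ValueError(f"ragged alignment, offending ids: {bad}")
        ids = [sid for sid, _ in rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        self.rows = [(sid, s.upper().replace(".", "-")) for sid, s in rows]
        self.n_cols = len(self.rows[0][1])
        self._index = {sid: i for i, (sid, _) in enumerate(self.rows)}

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]][1]

    def column(self, col: int) -> str:
        """Characters of a 1-based column, top to bottom."""
        if not (1 <= col <= self.n_cols):
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return "".join(s[col - 1] for _, s in self.rows)

    def write(self, stream: TextIO) -> None:
        for sid, s in self.rows:
            stream.write(f">{sid}\n{s}\n")


def read_alignment(fasta_stream: TextIO | str) -> Alignment:
    """Read an aligned FASTA; uppercases and normalizes '.' gaps to '-'."""
    if isinstance(fasta_stream, str):
        fasta_stream = io.StringIO(fasta_stream)
    rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fasta_stream, "fasta")]
    return Alignment(rows)


def _ungapped_index_per_column(row: str) -> list[int | None]:
    """For each column (0-based list), the 1-based ungapped residue index, or None."""
    out: list[int | None] = []
    n = 0
    for ch in row:
        if ch == "-":
            out.append(None)
        else:
            n += 1
            out.append(n)
    return out


@dataclass
class ColumnMap:
    """Per combined-alignment column: the matching subfamily column or None.

    ``support[c]`` is the fraction of voting shared sequences that agreed on
    the recorded target (or on the best candidate when the vote tied and the
    column was left unmapped).
    """

    target: dict[int, int | None]
    support: dict[int, float]

    def mapped_columns(self) -> list[int]:
        return [c for c, t in sorted(self.target.items()) if t is not None]

    def write_tsv(self, stream: TextIO) -> None:
        stream.write("combined_col\ttarget_col\tsupport\n")
        for c in sorted(self.target):
            t = self.target[c]
            stream.write(f"{c}\t{'' if t is None else t}\t{self.support[c]:.3f}\n")


def build_column_map(combined: Alignment, subfamily: Alignment) -> ColumnMap:
    """Map combined-alignment columns onto subfamily-alignment columns.

    For every sequence present in both alignments, a combined column and a
    subfamily column correspond when they hold the same ungapped residue of
    that sequence. Per column the target is decided by majority vote across
    the shared sequences that are not gapped there; a tied vote leaves the
    column unmapped (support records the best candidate's share). Columns
    gapped in every shared sequence are unmapped with support 0. The mapping
    is made injective: if two combined columns would claim the same target,
    only the better-supported one keeps it.
    """
    shared = [sid for sid in combined.ids if sid in set(subfamily.ids)]
    if not shared:
        raise ValueError("no shared sequence ids between alignments")

    # per shared sequence: subfamily column for each ungapped residue index
    sub_col_of_res: dict[str, dict[int, int]] = {}
    for sid in shared:
        idx = _ungapped_index_per_column(subfamily.row(sid))
        sub_col_of_res[sid] = {r: c + 1 for c, r in enumerate(idx) if r is not None}

    comb_idx = {sid: _ungapped_index_per_column(combined.row(sid)) for sid in shared}

    target: dict[int, int | None] = {}
    support: dict[int, float] = {}
    for c in range(1, combined.n_cols + 1):
        votes: Counter[int] = Counter()
        for sid in shared:
            r = comb_idx[sid][c - 1]
            if r is None:
                continue
            sub_c = sub_col_of_res[sid].get(r)
            if sub_c is not None:
                votes[sub_c] += 1
        if not votes:
            target[c], support[c] = None, 0.0
            continue
        total = sum(votes.values())
        (best, best_n), = votes.most_common(1)
        tied = [t for t, n in votes.items() if n == best_n]
        if len(tied) > 1:
            target[c], support[c] = None, best_n / total
        else:
            target[c], support[c] = best, best_n / total

    # enforce injectivity: keep the better-supported claimant
    claimed: dict[int, int] = {}
    for c in sorted(target):
        t = target[c]
        if t is None:
            continue
        prev = claimed.get(t)
        if prev is None:
            claimed[t] = c
        elif support[c] > support[prev]:
            target[prev] = None
            claimed[t] = c
        else:
            target[c] = None
    return ColumnMap(target, support)


def column_to_reference(
    alignment: Alignment, seq_id: str, column: int, numbering_offset: int = 0
) -> ResidueRef | None:
    """Translate a 1-based column into a residue of the reference row.

    Returns None when the reference row is gapped at that column; otherwise
    the residue number is the row's ungapped index plus ``numbering_offset``
    (used to express positions in, e.g., PDB author numbering).
    """
    row = alignment.row(seq_id)
    if not (1 <= column <= alignment.n_cols):
        raise IndexError(f"column {column} out of range 1..{alignment.n_cols}")
    ch = row[column - 1]
    if ch == "-":
        return None
    ungapped = sum(1 for x in row[:column] if x != "-")
    return ResidueRef(seq_id=seq_id, number=ungapped + numbering_offset, amino_acid=ch)
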