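"""Sequence and alignment I/O.

Sequences are plain FASTA; alignments are either aligned FASTA (every
column written with ``-`` gaps, all residues uppercase) or A2M (match
columns uppercase with ``-`` gaps, insert columns lowercase with ``.``
padding).  Pairwise alignments induced from an MSA drive the supervised
pretraining of the residue-pair scoring model.

Coordinates are 0-based and intervals half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, in the conventional alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Catch-all symbol for non-standard residues.
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + UNKNOWN

_NONSTANDARD = set("BZJUO*.")


@dataclass(frozen=True)
class Sequence:
    """An unaligned protein sequence over the 20-letter alphabet plus 'X'."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"zero-length sequence {self.identifier!r}")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped strings with per-column match flags.

    Match columns hold uppercase residues or ``-``; insert columns hold
    lowercase residues or a gap.  De-gapping any row must reproduce the
    underlying unaligned sequence.
    """

    identifiers: list[str]
    rows: list[str]
    match_columns: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.identifiers) != len(self.rows):
            raise ValueError("identifier/row count mismatch")
        if self.rows:
            w = len(self.rows[0])
            if any(len(r) != w for r in self.rows):
                raise ValueError("alignment rows have unequal lengths")
            if not self.match_columns:
                self.match_columns = [True] * w
            if len(self.match_columns) != w:
                raise ValueError("match_columns length mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, index: int) -> str:
        """Ungapped, uppercased content of row ``index``."""
        return "".join(
            c for c in self.rows[index] if c not in "-."
        ).upper()

    def column_residue_indices(self) -> list[dict[int, int]]:
        """Per column, a map row -> 0-based residue index (non-gap cells only)."""
        counters = [0] * self.n_rows
        out: list[dict[int, int]] = []
        for c in range(self.n_columns):
            col: dict[int, int] = {}
            for r in range(self.n_rows):
                ch = self.rows[r][c]
                if ch not in "-.":
                    col[r] = counters[r]
                    counters[r] += 1
            out.append(col)
        return out


@dataclass
class PairwiseAlignment:
    """Monotone list of aligned 0-based residue index pairs between two sequences."""

    id_a: str
    id_b: str
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if not (i1 > i0 and j1 > j0):
                raise ValueError("aligned index pairs must be strictly increasing")


def normalize_residues(raw: str) -> str:
    """Uppercase and map non-standard symbols to 'X'; strip a terminal '*'."""
    s = raw.upper().strip()
    if s.endswith("*"):
        s = s[:-1]
    return "".join(UNKNOWN if c in _NONSTANDARD or c not in ALPHABET else c for c in s)


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read unaligned sequences from a FASTA file, normalizing residues."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate identifiers in {path}: {dupes}")
    out = []
    for rec in records:
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise ValueError(f"zero-length record {rec.id!r} in {path}")
        out.append(Sequence(rec.id, residues))
    return out


def write_fasta(seqs: list[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_alignment(msa: MultipleAlignment, path: str | Path, dialect: str = "aligned-fasta") -> None:
    """Write an alignment as aligned FASTA or A2M.

    aligned-fasta: every cell uppercase or ``-``.  a2m: match columns
    uppercase/'-', insert columns lowercase/'.'.
    """
    if msa.n_rows == 0:
        raise ValueError("refusing to write an empty alignment")
    if dialect not in ("aligned-fasta", "a2m"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    lines = []
    for ident, row in zip(msa.identifiers, msa.rows):
        cells = []
        for c, ch in enumerate(row):
            is_match = msa.match_columns[c]
            if dialect == "aligned-fasta":
                cells.append("-" if ch in "-." else ch.upper())
            elif is_match:
                cells.append("-" if ch in "-." else ch.upper())
            else:
                cells.append("." if ch in "-." else ch.lower())
        lines.append(f">{ident}\n{''.join(cells)}\n")
    Path(path).write_text("".join(lines))


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> MultipleAlignment:
    """Read an alignment file.

    For A2M, columns containing ``.`` or any lowercase character are
    insert columns; everything else is a match column.  For aligned
    FASTA all columns are match columns.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    if len(set(len(r) for r in rows)) > 1:
        raise ValueError("alignment rows have unequal lengths")
    width = len(rows[0])
    if dialect == "a2m":
        match_cols = [
            not any(rows[r][c] == "." or rows[r][c].islower() for r in range(len(rows)))
            for c in range(width)
        ]
    else:
        rows = [r.upper().replace(".", "-") for r in rows]
        match_cols = [True] * width
    return MultipleAlignment(ids, rows, match_cols)


def induce_pairwise_alignments(msa: MultipleAlignment) -> list[PairwiseAlignment]:
    """Project an MSA onto all unordered row pairs.

    Two residues are aligned iff they share a column in which neither
    row has a gap; the resulting index lists are monotone by
    construction.
    """
    cols = msa.column_residue_indices()
    out = []
    for a, b in combinations(range(msa.n_rows), 2):
        pairs = [(col[a], col[b]) for col in cols if a in col and b in col]
        out.append(PairwiseAlignment(msa.identifiers[a], msa.identifiers[b], pairs))
    return out
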