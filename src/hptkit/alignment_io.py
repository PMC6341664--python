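"""Reading, writing and coordinate mapping of multiple sequence alignments.

Alignments are gapped rows of equal length keyed by sequence id, as in a
Pfam family alignment. On input every row is normalised to a single
alphabet: ``.`` and lowercase letters (Stockholm insert states) become
``-`` / uppercase, and the ambiguous letters B, Z, J, U, O become ``X``.
Alignment columns are 0-based internally; ungapped residue positions are
1-based, matching how positions are quoted for a protein sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: letters normalised to 'X' (ambiguity codes and rare residues)
_TO_X = str.maketrans({c: "X" for c in "BZJUO"})
_ALLOWED = frozenset(AMINO_ACIDS + "X" + GAP)


class AlignmentFormatError(ValueError):
    """Raised when an input file violates the alignment format contract."""


def normalize_row(row: str) -> str:
    """Normalise one aligned row: '.'/lowercase -> '-'/uppercase, B/Z/J/U/O -> 'X'.

    Raises :class:`AlignmentFormatError` naming the first illegal character
    and its 0-based column if anything outside the residue/gap alphabet
    survives normalisation.
    """
    out = row.replace(".", GAP).upper().translate(_TO_X)
    for i, c in enumerate(out):
        if c not in _ALLOWED:
            raise AlignmentFormatError(
                f"illegal character {c!r} at column {i} after normalization"
            )
    return out


@dataclass
class AlignedSequence:
    """One gapped row of an alignment."""

    id: str
    row: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.row) - _ALLOWED
        if bad:
            raise AlignmentFormatError(
                f"row for {self.id!r} contains unnormalized characters {sorted(bad)}"
            )

    def ungapped(self) -> str:
        return self.row.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered set of equal-length gapped rows with unique ids."""

    rows: list[AlignedSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one sequence")
        n = len(self.rows[0].row)
        for r in self.rows:
            if len(r.row) != n:
                raise AlignmentFormatError(
                    f"ragged alignment: row {r.id!r} has length {len(r.row)}, expected {n}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].row)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.rows)

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def subset(self, keep_ids) -> "Alignment":
        keep = set(keep_ids)
        return Alignment([r for r in self.rows if r.id in keep])


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith("# STOCKHOLM"):
                    return "stockholm"
                if line.startswith(">"):
                    return "fasta"
                raise AlignmentFormatError(
                    f"cannot sniff alignment format of {path}: "
                    f"expected '# STOCKHOLM' header or '>' record"
                )
    raise AlignmentFormatError(f"empty alignment file: {path}")


def read_alignment(path, format: str = "auto") -> Alignment:
    """Read a Stockholm or aligned-FASTA file into an :class:`Alignment`.

    ``format='auto'`` sniffs the Stockholm header versus '>' records.
    Rows are normalised (see :func:`normalize_row`); input order is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise AlignmentFormatError(f"empty alignment file: {path}")
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("stockholm", "fasta"):
        raise ValueError(f"unknown alignment format {format!r}")

    if format == "fasta":
        # SeqIO rather than AlignIO so a ragged file can be reported by id
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        records = list(AlignIO.read(str(path), "stockholm"))
    if not records:
        raise AlignmentFormatError(f"no sequences parsed from {path}")

    rows = []
    for rec in records:
        try:
            row = normalize_row(str(rec.seq))
        except AlignmentFormatError as e:
            raise AlignmentFormatError(f"sequence {rec.id!r}: {e}") from e
        rows.append(
            AlignedSequence(rec.id, row, rec.description or None)
        )
    n = len(rows[0].row)
    for r in rows:
        if len(r.row) != n:
            raise AlignmentFormatError(
                f"ragged alignment in {path}: row {r.id!r} has length "
                f"{len(r.row)}, expected {n}"
            )
    return Alignment(rows)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or Stockholm.

    ``read_alignment(write_alignment(aln))`` reproduces ids and rows exactly.
    """
    if format not in ("stockholm", "fasta"):
        raise ValueError(f"unknown alignment format {format!r}")
    records = [
        SeqRecord(Seq(r.row), id=r.id, description=r.description or "")
        for r in aln
    ]
    msa = MultipleSeqAlignment(records)
    AlignIO.write(msa, str(path), format)


GAP_MARKER = None  #: value used for gap columns in column/position maps


@dataclass(frozen=True)
class ColumnPositionMap:
    """Bidirectional map between alignment columns and ungapped positions.

    ``col_to_pos[c]`` is the 1-based ungapped residue position at 0-based
    column ``c``, or ``None`` (:data:`GAP_MARKER`) when the column is a gap.
    ``pos_to_col[p]`` inverts it for positions 1..ungapped length.
    """

    col_to_pos: tuple
    pos_to_col: tuple

    @property
    def ungapped_length(self) -> int:
        return len(self.pos_to_col)

    def position(self, col: int):
        return self.col_to_pos[col]

    def column(self, pos: int) -> int:
        return self.pos_to_col[pos - 1]


def column_to_position_map(seq: AlignedSequence) -> ColumnPositionMap:
    """Map each alignment column of one row to its ungapped residue position."""
    col_to_pos = []
    pos_to_col = []
    pos = 0
    for c, ch in enumerate(seq.row):
        if ch == GAP:
            col_to_pos.append(GAP_MARKER)
        else:
            pos += 1
            col_to_pos.append(pos)
            pos_to_col.append(c)
    return ColumnPositionMap(tuple(col_to_pos), tuple(pos_to_col))
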