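"""Anchor-relative residue conservation census for HPt family alignments.

The pipeline mirrors how a family-wide census of the residue four positions
downstream of the phosphorylatable histidine (the "H+4" position) is done
on a fixed master alignment:

1. greedy redundancy removal at a percent-identity threshold (default 98%),
2. location of the anchor column — the alignment column carrying the
   conserved histidine — and removal of rows lacking the anchor residue,
3. a census of the residue k positions downstream of the anchor in
   *ungapped* sequence coordinates (gap columns are skipped), and
4. a percent-of-total table, plus sequence-logo information content.

Percent identity between two rows is the number of identical residues over
the columns where both rows are non-gap ('X' never counts as a match);
there is no realignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .alignment_io import AMINO_ACIDS, GAP, AlignedSequence, Alignment

TOO_SHORT = "too-short"
LOG2_20 = math.log2(20.0)


# ---------------------------------------------------------------------------
# redundancy removal


@dataclass
class RedundancyResult:
    kept_ids: list[str]
    clusters: dict[str, list[str]]
    threshold: float


def _row_array(seq: AlignedSequence) -> np.ndarray:
    return np.frombuffer(seq.row.encode("ascii"), dtype="S1")


def pairwise_identity(a: AlignedSequence, b: AlignedSequence) -> float:
    """Fraction of mutually aligned (both non-gap) columns that match.

    'X' placeholders sit in the denominator but never match. Returns 0.0
    when the rows share no mutually aligned column.
    """
    if len(a.row) != len(b.row):
        raise ValueError(
            f"alignment length mismatch: {a.id!r} has {len(a.row)}, "
            f"{b.id!r} has {len(b.row)}"
        )
    ra, rb = _row_array(a), _row_array(b)
    both = (ra != b"-") & (rb != b"-")
    n = int(both.sum())
    if n == 0:
        return 0.0
    matches = int(((ra == rb) & both & (ra != b"X")).sum())
    return matches / n


def remove_redundancy(aln: Alignment, threshold: float = 0.98) -> RedundancyResult:
    """Greedy single-pass identity clustering in input row order.

    Each row joins the first existing cluster whose *representative* has
    identity >= threshold to it, else founds a new cluster. Deterministic
    for a given row order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    reps: list[AlignedSequence] = []
    rep_arrays: list[np.ndarray] = []
    rep_nongap: list[np.ndarray] = []
    clusters: dict[str, list[str]] = {}
    for seq in aln:
        arr = _row_array(seq)
        nongap = arr != b"-"
        assigned = False
        for rep, rarr, rng in zip(reps, rep_arrays, rep_nongap):
            both = nongap & rng
            n = int(both.sum())
            if n == 0:
                continue
            matches = int(((arr == rarr) & both & (arr != b"X")).sum())
            if matches / n >= threshold:
                clusters[rep.id].append(seq.id)
                assigned = True
                break
        if not assigned:
            reps.append(seq)
            rep_arrays.append(arr)
            rep_nongap.append(nongap)
            clusters[seq.id] = [seq.id]
    return RedundancyResult([r.id for r in reps], clusters, threshold)


# ---------------------------------------------------------------------------
# anchor detection and the H+k census


@dataclass
class AnchorResult:
    anchor_col: int
    anchor_freq: float
    removed_ids: list[str]


class NoConservedAnchorError(ValueError):
    """No alignment column carries the anchor residue often enough."""


def find_anchor_column(
    aln: Alignment, anchor_residue: str = "H", min_freq: float = 0.5
) -> AnchorResult:
    """Locate the column maximising the frequency of ``anchor_residue``.

    Ties break to the lowest column index. Rows lacking the anchor residue
    at that column are listed in ``removed_ids`` for the caller to drop.
    """
    mat = np.array([_row_array(r) for r in aln])
    hits = mat == anchor_residue.encode("ascii")
    freqs = hits.mean(axis=0)
    col = int(np.argmax(freqs))  # argmax takes the first maximum
    best = float(freqs[col])
    if best < min_freq:
        raise NoConservedAnchorError(
            f"no conserved anchor: best {anchor_residue!r} column frequency "
            f"{best:.3f} < {min_freq}"
        )
    removed = [r.id for r, hit in zip(aln, hits[:, col]) if not hit]
    return AnchorResult(col, best, removed)


def residue_at_offset(seq: AlignedSequence, anchor_col: int, k: int) -> str:
    """Residue k positions downstream of the anchor in ungapped coordinates.

    Gap columns are skipped; returns :data:`TOO_SHORT` when the sequence
    ends before reaching the offset.
    """
    if seq.row[anchor_col] == GAP:
        raise ValueError(f"sequence {seq.id!r} has a gap at anchor column {anchor_col}")
    remaining = k
    for c in range(anchor_col + 1, len(seq.row)):
        ch = seq.row[c]
        if ch == GAP:
            continue
        remaining -= 1
        if remaining == 0:
            return ch
    return TOO_SHORT


@dataclass
class PositionCount:
    """Residue counts at an anchor-relative offset (k in "H+k")."""

    offset_k: int
    counts: dict[str, int] = field(default_factory=dict)
    n_short: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_offset_residues(
    aln: Alignment, anchor: AnchorResult, k: int = 4
) -> PositionCount:
    """Census of the residue at anchor+k over rows retaining the anchor.

    Rows in ``anchor.removed_ids`` are excluded; rows whose sequence ends
    within k residues of the anchor are tallied in ``n_short`` only.
    """
    removed = set(anchor.removed_ids)
    counts: dict[str, int] = {}
    n_short = 0
    for seq in aln:
        if seq.id in removed:
            continue
        res = residue_at_offset(seq, anchor.anchor_col, k)
        if res == TOO_SHORT:
            n_short += 1
        else:
            counts[res] = counts.get(res, 0) + 1
    return PositionCount(k, counts, n_short)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits), ROUND_HALF_UP))


def percent_table(pc: PositionCount, exclude_x: bool = False) -> pd.DataFrame:
    """Percent-of-total table, sorted by count descending.

    Columns: residue, count, percent (half-up rounded to 2 decimals).
    ``exclude_x`` drops 'X' placeholders from the denominator and table.
    """
    counts = dict(pc.counts)
    if exclude_x:
        counts.pop("X", None)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot compute percentages: total count is zero")
    rows = [
        (res, n, _round_half_up(100.0 * n / total))
        for res, n in counts.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["residue", "count", "percent"])


def run_census(
    aln: Alignment,
    threshold: float = 0.98,
    anchor_residue: str = "H",
    k: int = 4,
    min_freq: float = 0.5,
):
    """Full pipeline: redundancy -> anchor -> H+k census.

    Returns (RedundancyResult, AnchorResult, PositionCount, percent table).
    """
    red = remove_redundancy(aln, threshold)
    nonred = aln.subset(red.kept_ids)
    anchor = find_anchor_column(nonred, anchor_residue, min_freq)
    pc = count_offset_residues(nonred, anchor, k)
    return red, anchor, pc, percent_table(pc)


# ---------------------------------------------------------------------------
# sequence-logo information content


@dataclass
class LogoColumn:
    col: int
    freqs: dict[str, float]
    n_obs: int
    info_bits: Optional[float]
    heights: dict[str, float]


def logo_matrix(
    aln: Alignment, small_sample_correction: bool = False
) -> list[LogoColumn]:
    """Per-column gap-excluded frequencies and information content in bits.

    info = log2(20) - H - e_n, where H is the Shannon entropy of the
    gap-excluded column frequencies and e_n = (s-1)/(2·n·ln 2) with s=20
    when the small-sample correction is on (else 0); clamped at 0.
    Letter heights are freq·info. Columns with no residues report
    ``info_bits=None``.
    """
    cols = []
    alphabet = AMINO_ACIDS + "X"
    for c in range(aln.n_cols):
        column = [r.row[c] for r in aln if r.row[c] != GAP]
        n = len(column)
        if n == 0:
            cols.append(LogoColumn(c, {}, 0, None, {}))
            continue
        freqs: dict[str, float] = {}
        for ch in column:
            freqs[ch] = freqs.get(ch, 0) + 1
        freqs = {a: v / n for a, v in freqs.items() if a in alphabet}
        h = -sum(p * math.log2(p) for p in freqs.values() if p > 0)
        e_n = (20 - 1) / (2 * n * math.log(2)) if small_sample_correction else 0.0
        info = max(0.0, LOG2_20 - h - e_n)
        heights = {a: p * info for a, p in freqs.items()}
        cols.append(LogoColumn(c, freqs, n, info, heights))
    return cols


def logo_dataframe(columns: list[LogoColumn]) -> pd.DataFrame:
    """Flatten logo columns to a tidy table: col, residue, freq, info_bits, height."""
    rows = []
    for lc in columns:
        if lc.info_bits is None:
            continue
        for res in sorted(lc.freqs):
            rows.append((lc.col, res, lc.freqs[res], lc.info_bits, lc.heights[res]))
    return pd.DataFrame(rows, columns=["col", "residue", "freq", "info_bits", "height"])
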