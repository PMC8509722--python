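"""Repeat-domain self-alignment and internal conservation profiling.

Repeat proteins (e.g. the four YWTD β-propellers of LRP5) are poorly served
by cross-species conservation analysis because the repeated units diverge
within the protein itself. The self-analysis implemented here aligns the
protein's own repeat units against each other and scores, per alignment
column, how internally conserved each position is — highlighting positions
whose identity is maintained across all copies of the unit and which are
therefore plausibly required for the repeat fold.

Alignment scheme: BLOSUM62 substitutions, affine gaps (a gap of length k
costs ``GAP_OPEN + k * GAP_EXTEND`` = -(10 + k)). Units are aligned
progressively in input order against a growing profile; a residue is scored
against a profile column as the mean substitution value over the column's
rows, with gap rows contributing the gap-extend penalty. Traceback ties
break deterministically: match first, then gap in the second sequence, then
gap in the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import substitution_matrices

__all__ = [
    "RepeatUnitSet",
    "UnitAlignment",
    "ConservationProfile",
    "GAP_OPEN",
    "GAP_EXTEND",
    "segment_units",
    "pairwise_unit_align",
    "self_align",
    "conservation_profile",
]

GAP_OPEN = -10.0
GAP_EXTEND = -1.0

_BLOSUM = substitution_matrices.load("BLOSUM62")
#: plain dict of BLOSUM62 values keyed by residue pair
BLOSUM62: dict[tuple[str, str], float] = {
    (a, b): float(_BLOSUM[a, b]) for a in _BLOSUM.alphabet for b in _BLOSUM.alphabet
}

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class RepeatUnitSet:
    """Repeat units of one protein: (start, end, sequence), 1-based inclusive."""

    protein_id: str
    units: tuple[tuple[int, int, str], ...]

    def __post_init__(self):
        if len(self.units) < 2:
            raise ValueError("self-analysis requires at least 2 repeat units")

    @property
    def sequences(self) -> list[str]:
        return [u[2] for u in self.units]


@dataclass(frozen=True)
class UnitAlignment:
    """Gapped unit sequences of equal length."""

    rows: tuple[str, ...]
    score: float = 0.0

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    def ungapped(self) -> list[str]:
        return [r.replace("-", "") for r in self.rows]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column internal conservation scores and the consensus unit."""

    scores: tuple[float, ...]
    consensus: str

    def __post_init__(self):
        if len(self.scores) != len(self.consensus):
            raise ValueError("scores and consensus must have equal length")
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise ValueError("conservation scores must lie in [0, 1]")


def segment_units(protein: str, boundaries: Sequence[tuple[int, int]]) -> RepeatUnitSet:
    """Cut ``protein`` into repeat units at 1-based inclusive ``boundaries``."""
    if len(boundaries) < 2:
        raise ValueError("self-analysis requires at least 2 unit boundaries")
    prev_end = 0
    units = []
    for start, end in boundaries:
        if start <= prev_end:
            raise ValueError(f"boundary ({start}, {end}) overlaps or is unsorted")
        if start < 1 or end > len(protein) or start > end:
            raise ValueError(f"boundary ({start}, {end}) outside protein of length {len(protein)}")
        units.append((start, end, protein[start - 1 : end]))
        prev_end = end
    return RepeatUnitSet(protein_id="", units=tuple(units))


def _column_score(column: Sequence[str], residue: str) -> float:
    """Mean substitution value of ``residue`` against a profile column."""
    total = 0.0
    for sym in column:
        total += GAP_EXTEND if sym == "-" else BLOSUM62[sym, residue]
    return total / len(column)


def _align_profile(rows: Sequence[str], seq: str) -> tuple[list[str], str, float]:
    """Affine-gap global alignment of a gapped profile against one sequence.

    Returns the re-gapped profile rows, the gapped new row, and the score.
    Gotoh three-state DP; all state transitions permitted with the opening
    penalty charged whenever a new gap run starts.
    """
    ncols = len(rows[0])
    cols = [[r[j] for r in rows] for j in range(ncols)]
    n, m = len(seq), ncols

    # state matrices indexed [i][j]: i residues of seq, j profile columns consumed
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq (consume column)
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in profile (consume residue)
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = GAP_OPEN + j * GAP_EXTEND
    for i in range(1, n + 1):
        Y[i][0] = GAP_OPEN + i * GAP_EXTEND

    for i in range(1, n + 1):
        res = seq[i - 1]
        for j in range(1, m + 1):
            M[i][j] = _column_score(cols[j - 1], res) + max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            )
            X[i][j] = GAP_EXTEND + max(
                X[i][j - 1], GAP_OPEN + M[i][j - 1], GAP_OPEN + Y[i][j - 1]
            )
            Y[i][j] = GAP_EXTEND + max(
                Y[i - 1][j], GAP_OPEN + M[i - 1][j], GAP_OPEN + X[i - 1][j]
            )

    score = max(M[n][m], X[n][m], Y[n][m])

    # traceback; tie-break: match, then gap-in-seq (consume column), then gap-in-profile
    out_cols: list[list[str]] = []
    out_seq: list[str] = []
    i, j = n, m
    if M[n][m] >= X[n][m] and M[n][m] >= Y[n][m]:
        state = "M"
    elif X[n][m] >= Y[n][m]:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            out_cols.append(cols[j - 1])
            out_seq.append(seq[i - 1])
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            i, j = i - 1, j - 1
        elif state == "X":
            out_cols.append(cols[j - 1])
            out_seq.append("-")
            prev = (
                GAP_OPEN + M[i][j - 1],
                X[i][j - 1],
                GAP_OPEN + Y[i][j - 1],
            )
            j = j - 1
        else:
            out_cols.append(["-"] * len(rows))
            out_seq.append(seq[i - 1])
            prev = (
                GAP_OPEN + M[i - 1][j],
                GAP_OPEN + X[i - 1][j],
                Y[i - 1][j],
            )
            i = i - 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "X"
        elif j == 0:
            state = "Y"
        else:
            best = max(prev)
            state = "M" if prev[0] == best else ("X" if prev[1] == best else "Y")

    out_cols.reverse()
    out_seq.reverse()
    new_rows = ["".join(col[k] for col in out_cols) for k in range(len(rows))]
    return new_rows, "".join(out_seq), score


def pairwise_unit_align(a: str, b: str) -> UnitAlignment:
    """Optimal global alignment of two unit sequences (affine gaps, BLOSUM62)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    rows, new_row, score = _align_profile([a], b)
    return UnitAlignment(rows=(rows[0], new_row), score=score)


def self_align(units: RepeatUnitSet) -> UnitAlignment:
    """Progressively align repeat units (input order) into one alignment."""
    seqs = units.sequences
    rows = [seqs[0]]
    score = 0.0
    for seq in seqs[1:]:
        rows, new_row, score = _align_profile(rows, seq)
        rows = rows + [new_row]
    return UnitAlignment(rows=tuple(rows), score=score)


def conservation_profile(aln: UnitAlignment) -> ConservationProfile:
    """Gap-aware per-column conservation of a unit alignment.

    Column score = (modal non-gap residue frequency among non-gap symbols)
    x (non-gap fraction of the column), so insertion columns present in only
    a few units score low. The consensus symbol is the modal residue, or '-'
    where gaps hold the majority; residue ties break alphabetically.
    """
    scores = []
    consensus = []
    nrows = len(aln.rows)
    for j in range(aln.column_count):
        col = aln.column(j)
        residues = [s for s in col if s != "-"]
        if not residues:
            scores.append(0.0)
            consensus.append("-")
            continue
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        modal = min(r for r, c in counts.items() if c == max(counts.values()))
        nongap_frac = len(residues) / nrows
        scores.append(counts[modal] / len(residues) * nongap_frac)
        consensus.append(modal if len(residues) * 2 >= nrows else "-")
    return ConservationProfile(scores=tuple(scores), consensus="".join(consensus))
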