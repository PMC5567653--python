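"""Column-level analytics on protein multiple alignments.

Columns are 1-based and intervals closed, matching the residue-numbering
style used when reporting signature positions against a reference
homolog.  "Conserved" means: consensus residue frequency at or above a
threshold (default 0.8) over the compared rows, with no gap among those
rows at that column (a gap vetoes conservation so an indel cannot count
toward its own flank evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AMBIG = set("XBZU")
_ALLOWED = set(_AA20) | _AMBIG | {"-"}


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Rectangular gapped residue matrix with unique row ids."""

    ids: list
    rows: list

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate row ids")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"row {rid!r} has length {len(row)}, expected {width}")
            bad = set(row) - _ALLOWED
            if bad:
                raise AlignmentError(f"row {rid!r}: invalid characters {sorted(bad)}")

    @property
    def nrows(self) -> int:
        return len(self.rows)

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    @cached_property
    def array(self) -> np.ndarray:
        """(nrows, ncols) array of single-byte characters."""
        return np.frombuffer("".join(self.rows).encode(),
                             dtype="S1").reshape(self.nrows, self.ncols)

    @cached_property
    def _index(self) -> dict:
        return {rid: i for i, rid in enumerate(self.ids)}

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self._index[seq_id]]
        except KeyError:
            raise AlignmentError(f"unknown sequence id {seq_id!r}") from None

    def row_index(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise AlignmentError(f"unknown sequence id {seq_id!r}") from None

    def column(self, col: int) -> str:
        self._check_col(col)
        return "".join(row[col - 1] for row in self.rows)

    def _check_col(self, col: int) -> None:
        if not 1 <= col <= self.ncols:
            raise AlignmentError(f"column {col} out of range 1..{self.ncols}")

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f"{rid}\t{row}\n")


@dataclass
class ColumnProfile:
    column: int
    frequencies: dict
    consensus: str
    consensus_fraction: float
    gap_fraction: float


def column_profile(aln: Alignment, col: int) -> ColumnProfile:
    """Residue profile of one column.

    Frequencies are over non-gap characters; ambiguity codes (X/B/Z/U)
    appear in the frequency table but never as consensus, and the
    consensus fraction is over the canonical residue count.  Consensus
    ties break alphabetically.
    """
    aln._check_col(col)
    chars = aln.column(col)
    nongap = [c for c in chars if c != "-"]
    canonical = [c for c in nongap if c not in _AMBIG]
    freqs: dict[str, float] = {}
    if nongap:
        for c in sorted(set(nongap)):
            freqs[c] = nongap.count(c) / len(nongap)
    if canonical:
        counts = {c: canonical.count(c) for c in set(canonical)}
        best = max(counts.values())
        # alphabetical tie-break
        consensus = sorted(c for c, n in counts.items() if n == best)[0]
        consensus_fraction = best / len(canonical)
    else:
        consensus, consensus_fraction = "", 0.0
    gap_fraction = chars.count("-") / len(chars)
    return ColumnProfile(col, freqs, consensus, consensus_fraction, gap_fraction)


def is_conserved(aln: Alignment, col: int, subset=None, threshold: float = 0.8) -> bool:
    """True iff the column's consensus fraction over ``subset`` rows
    reaches ``threshold`` and no subset row is gapped there (gap-veto)."""
    if not 0.5 < threshold <= 1.0:
        raise AlignmentError(f"threshold {threshold} outside (0.5, 1]")
    aln._check_col(col)
    if subset is None:
        idx = range(aln.nrows)
    else:
        subset = list(subset)
        if not subset:
            raise AlignmentError("empty subset")
        idx = [aln.row_index(s) for s in subset]
    chars = [aln.rows[i][col - 1] for i in idx]
    if "-" in chars:
        return False
    canonical = [c for c in chars if c not in _AMBIG]
    if not canonical:
        return False
    best = max(canonical.count(c) for c in set(canonical))
    return best / len(canonical) >= threshold


def strip_gap_columns(aln: Alignment):
    """Drop every column containing at least one gap.

    Returns the stripped alignment and the (1-based) removed columns.
    Mirrors complete-deletion treatment before tree building.
    """
    arr = aln.array
    has_gap = (arr == b"-").any(axis=0)
    kept = np.flatnonzero(~has_gap)
    if kept.size == 0:
        raise AlignmentError("all columns contain gaps; nothing left to analyse")
    removed = [int(i) + 1 for i in np.flatnonzero(has_gap)]
    sub = arr[:, kept]
    rows = [b"".join(sub[i]).decode() for i in range(aln.nrows)]
    return Alignment(ids=list(aln.ids), rows=rows), removed


@dataclass
class ReferenceMap:
    """Alignment column <-> ungapped residue number of a reference row."""

    ref_id: str
    col_to_res: list            # length ncols; int residue number or None
    res_to_col: dict = field(default_factory=dict)

    def residue_at(self, col: int):
        return self.col_to_res[col - 1]

    def column_of(self, residue: int) -> int:
        if residue not in self.res_to_col:
            raise AlignmentError(
                f"residue {residue} outside reference {self.ref_id!r}")
        return self.res_to_col[residue]

    def describe(self, col: int) -> str:
        """Human-readable anchor: residue number, or ``after n`` when the
        reference is gapped at ``col`` (signature loci inside reference
        gaps are reported as falling after the preceding residue)."""
        res = self.col_to_res[col - 1]
        if res is not None:
            return str(res)
        prev = 0
        for c in range(col - 1, 0, -1):
            r = self.col_to_res[c - 1]
            if r is not None:
                prev = r
                break
        return f"after {prev}"


def map_reference(aln: Alignment, ref_id: str) -> ReferenceMap:
    row = aln.row(ref_id)
    col_to_res: list = []
    res_to_col: dict[int, int] = {}
    n = 0
    for col, ch in enumerate(row, start=1):
        if ch == "-":
            col_to_res.append(None)
        else:
            n += 1
            col_to_res.append(n)
            res_to_col[n] = col
    return ReferenceMap(ref_id, col_to_res, res_to_col)


def pairwise_identity(aln: Alignment, id1: str, id2: str) -> float:
    """Fraction of identical residues over columns where both rows are
    non-gap (pairwise-deletion denominator)."""
    a = np.frombuffer(aln.row(id1).encode(), dtype="S1")
    b = np.frombuffer(aln.row(id2).encode(), dtype="S1")
    shared = (a != b"-") & (b != b"-")
    n = int(shared.sum())
    if n == 0:
        raise AlignmentError(
            f"rows {id1!r} and {id2!r} share no non-gap columns")
    return float((a[shared] == b[shared]).sum()) / n
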