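"""Conserved signature indel (CSI) detection and classification.

A CSI is a fixed-length insertion or deletion in a protein alignment
that is flanked on both sides by conserved residues (here: at least
``min_conserved`` conserved columns within a ``window`` of 30 positions,
the permissive end of the usual 5-6 within 30-40 rule) and whose
presence/absence pattern is uniform within one or more whole groups of
homologs and uniformly opposite outside them.

Because no outgroup exists for the eukaryotic DGK catalytic domain, the
ancestral state of any indel is unknowable; verdicts therefore carry
only *relative* polarity (``insert_relative`` / ``deletion_relative``
with respect to the compared homologs), never an ancestral inference.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, AlignmentError, ReferenceMap

logger = logging.getLogger(__name__)

_AMBIG = set("XBZU")

#: rendered in signature excerpts for a gap where the top row has a residue
GAP_GLYPH = "~"


@dataclass(frozen=True)
class GapRun:
    """Maximal run of gap characters in one row."""
    seq_id: str
    start: int           # 1-based, closed interval
    end: int
    touches_terminus: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class IndelLocus:
    """A cluster of overlapping gap runs: one candidate indel site."""
    start: int
    end: int
    runs: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def gap_lengths(self, aln: Alignment) -> dict:
        """Per-sequence count of gap characters inside the locus hull."""
        seg = aln.array[:, self.start - 1:self.end]
        gaps = (seg == b"-").sum(axis=1)
        return {rid: int(g) for rid, g in zip(aln.ids, gaps)}


@dataclass
class FlankAssessment:
    locus: IndelLocus
    window: int
    min_conserved: int
    left_conserved: int
    right_conserved: int
    passed: bool


@dataclass
class CsiCall:
    locus: IndelLocus
    verdict: str                      # group_specific | shared_by_groups |
                                      # paired_lengths | unclassified
    state: str                        # insert_relative | deletion_relative
    groups: dict                      # target group -> (len_min, len_max)
    flanks: FlankAssessment | None = None
    exceptions: int = 0
    ref_anchor: str = ""

    POLARITY_CAVEAT = ("insert/deletion polarity is relative to the compared "
                       "homologs only; no ancestral state is inferred")

    @property
    def length_range(self):
        los = [lo for lo, _ in self.groups.values()]
        his = [hi for _, hi in self.groups.values()]
        return (min(los), max(his)) if los else (0, 0)


def find_gap_runs(aln: Alignment) -> list[GapRun]:
    """All maximal gap runs, per row, in column order."""
    runs = []
    for rid, row in zip(aln.ids, aln.rows):
        for m in re.finditer(r"-+", row):
            start, end = m.start() + 1, m.end()
            runs.append(GapRun(rid, start, end,
                               touches_terminus=(start == 1 or end == aln.ncols)))
    return runs


def cluster_loci(runs, link_overlap: bool = True) -> list[IndelLocus]:
    """Merge overlapping gap runs (single linkage) into loci.

    Terminal runs are excluded first: ragged row ends reflect fragment
    boundaries, not indel events.
    """
    internal = sorted((r for r in runs if not r.touches_terminus),
                      key=lambda r: (r.start, r.end, r.seq_id))
    loci: list[IndelLocus] = []
    for run in internal:
        if (link_overlap and loci and run.start <= loci[-1].end):
            loci[-1].end = max(loci[-1].end, run.end)
            loci[-1].runs.append(run)
        else:
            loci.append(IndelLocus(run.start, run.end, [run]))
    return loci


def assess_flanks(aln: Alignment, locus: IndelLocus, window: int = 30,
                  min_conserved: int = 5, threshold: float = 0.8) -> FlankAssessment:
    """Count conserved columns in the windows flanking a locus.

    A flank column counts as conserved when (a) no row that is un-gapped
    at the locus is gapped there — rows gapped at the locus cannot veto,
    since their flanks may be disturbed by the indel itself — and (b) the
    consensus fraction over all rows' canonical residues reaches
    ``threshold``.
    """
    if not 10 <= window <= 60:
        raise AlignmentError(f"window {window} outside [10, 60]")
    if min_conserved < 1:
        raise AlignmentError("min_conserved must be >= 1")
    if locus.start < 1 or locus.end > aln.ncols:
        raise AlignmentError(
            f"locus [{locus.start},{locus.end}] outside alignment 1..{aln.ncols}")
    arr = aln.array
    seg = arr[:, locus.start - 1:locus.end]
    veto_rows = np.flatnonzero((seg == b"-").sum(axis=1) == 0)

    def count(cols) -> int:
        n = 0
        for c in cols:
            col = arr[:, c - 1]
            if veto_rows.size and (col[veto_rows] == b"-").any():
                continue
            vals = [ch.decode() for ch in col if ch != b"-"]
            canonical = [v for v in vals if v not in _AMBIG]
            if not canonical:
                continue
            best = max(canonical.count(v) for v in set(canonical))
            if best / len(canonical) >= threshold:
                n += 1
        return n

    left = count(range(max(1, locus.start - window), locus.start))
    right = count(range(locus.end + 1, min(aln.ncols, locus.end + window) + 1))
    passed = left >= min_conserved and right >= min_conserved
    return FlankAssessment(locus, window, min_conserved, left, right, passed)


def _group_state(lengths: list, width: int) -> tuple[str, int, int]:
    """Summarise one group's presence at a locus.

    Returns (kind, len_min, len_max) where lengths are *present* residue
    counts (width - gaps) and kind is one of absent / full /
    partial_uniform / mixed_positive / inconsistent.
    """
    present = [width - g for g in lengths]
    if all(p == 0 for p in present):
        return "absent", 0, 0
    if all(p == width for p in present):
        return "full", width, width
    if all(p > 0 for p in present):
        lo, hi = min(present), max(present)
        if lo == hi:
            return "partial_uniform", lo, hi
        return "mixed_positive", lo, hi
    return "inconsistent", min(present), max(present)


def classify_specificity(aln: Alignment, locus: IndelLocus, scheme,
                         grouping: str = "by_class",
                         exceptions: int = 0) -> CsiCall:
    """Assign a group-specificity verdict to one indel locus.

    The background is whichever side — groups uniformly carrying the
    full segment, or groups uniformly lacking it — comprises more
    groups (row-count tie-break); the remaining groups are the signature
    carriers.  Insert lengths may vary within a carrier group (reported
    as a range); deletion lengths must be group-uniform.
    """
    groups = scheme.groups(grouping, aln.ids)
    if len(groups) < 2:
        raise AlignmentError(
            f"grouping {grouping!r} yields {len(groups)} group(s); need >= 2")
    unlabeled = set(aln.ids) - {i for mem in groups.values() for i in mem}
    if unlabeled:
        logger.warning("classify_specificity: excluding %d unlabeled rows",
                       len(unlabeled))
    gaplen = locus.gap_lengths(aln)
    width = locus.width

    def attempt(members_of: dict) -> CsiCall | None:
        states = {}
        for lab, members in members_of.items():
            if not members:
                return None
            states[lab] = _group_state([gaplen[m] for m in members], width)
        if any(s[0] == "inconsistent" for s in states.values()):
            return None
        full = [g for g, s in states.items() if s[0] == "full"]
        absent = [g for g, s in states.items() if s[0] == "absent"]
        if not full and not absent:
            return None
        nrows_full = sum(len(members_of[g]) for g in full)
        nrows_absent = sum(len(members_of[g]) for g in absent)
        if (len(full), nrows_full) > (len(absent), nrows_absent):
            # deletion-type: background carries the segment in full
            targets = {g: s for g, s in states.items() if s[0] != "full"}
            if not targets:
                return None
            # deletions must have uniform gapped length within each group
            if any(s[0] == "mixed_positive" for s in targets.values()):
                return None
            lengths = {g: (width - s[2], width - s[1]) for g, s in targets.items()}
            state = "deletion_relative"
        elif (len(absent), nrows_absent) > (len(full), nrows_full):
            # insert-type: background lacks the segment entirely
            targets = {g: s for g, s in states.items() if s[0] != "absent"}
            if not targets:
                return None
            lengths = {g: (s[1], s[2]) for g, s in targets.items()}
            state = "insert_relative"
        else:
            return None
        if len(lengths) == 1:
            verdict = "group_specific"
        else:
            spans = set(lengths.values())
            if len(spans) == 1:
                verdict = "shared_by_groups"
            elif all(states[g][0] in ("partial_uniform", "full", "absent")
                     for g in lengths):
                verdict = "paired_lengths"
            else:
                verdict = "shared_by_groups"
        return CsiCall(locus, verdict, state, lengths)

    call = attempt(groups)
    if call is not None:
        return call

    if exceptions > 0:
        # drop rows deviating from their group's majority presence flag
        outliers = []
        for lab, members in groups.items():
            flags = [gaplen[m] < width for m in members]   # carries residues?
            majority = flags.count(True) >= flags.count(False)
            outliers += [m for m, f in zip(members, flags) if f != majority]
        if 0 < len(outliers) <= exceptions:
            reduced = {lab: [m for m in mem if m not in outliers]
                       for lab, mem in groups.items()}
            reduced = {lab: mem for lab, mem in reduced.items() if mem}
            if len(reduced) >= 2:
                call = attempt(reduced)
                if call is not None:
                    call.exceptions = len(outliers)
                    return call

    return CsiCall(locus, "unclassified", "insert_relative", {})


def scan(aln: Alignment, scheme, grouping: str = "by_class",
         window: int = 30, min_conserved: int = 5, threshold: float = 0.8,
         exceptions: int = 0, keep_unclassified: bool = False,
         refmap: ReferenceMap | None = None) -> list[CsiCall]:
    """Full CSI scan: gap runs -> loci -> flank filter -> specificity.

    Deterministic for fixed inputs; calls are ordered by locus start.
    """
    runs = find_gap_runs(aln)
    loci = cluster_loci(runs)
    calls = []
    for locus in loci:
        fa = assess_flanks(aln, locus, window, min_conserved, threshold)
        if not fa.passed:
            continue
        call = classify_specificity(aln, locus, scheme, grouping, exceptions)
        call.flanks = fa
        if call.verdict == "unclassified" and not keep_unclassified:
            continue
        if refmap is not None:
            call.ref_anchor = refmap.describe(locus.start)
        calls.append(call)
    return calls


def calls_to_tsv(calls, path) -> None:
    header = ("locus_start\tlocus_end\tref_anchor\tverdict\tgroups\tstate\t"
              "len_min\tlen_max\tflank_left\tflank_right\texceptions\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for c in calls:
            lo, hi = c.length_range
            groups = ",".join(f"{g}:{a}-{b}" if a != b else f"{g}:{a}"
                              for g, (a, b) in sorted(c.groups.items()))
            fl = c.flanks.left_conserved if c.flanks else ""
            fr = c.flanks.right_conserved if c.flanks else ""
            fh.write(f"{c.locus.start}\t{c.locus.end}\t{c.ref_anchor}\t"
                     f"{c.verdict}\t{groups}\t{c.state}\t{lo}\t{hi}\t"
                     f"{fl}\t{fr}\t{c.exceptions}\n")


def render_signature(aln: Alignment, call: CsiCall, context: int = 30,
                     refmaps=()) -> str:
    """Fixed-width excerpt around a call in dot-difference style.

    The top row is shown verbatim; in every other row ``-`` marks
    identity with the top row and ``~`` marks a gap where the top row
    has a residue (so the excerpt plus the top line reconstruct the
    original residues exactly).
    """
    a = max(1, call.locus.start - context)
    b = min(aln.ncols, call.locus.end + context)
    header = [f"# locus {call.locus.start}-{call.locus.end}  "
              f"verdict={call.verdict}  state={call.state}"]
    for rm in refmaps:
        header.append(f"# {rm.ref_id}: excerpt starts at {rm.describe(a)}")
    header.append(f"# note: {CsiCall.POLARITY_CAVEAT}")
    name_w = max(len(i) for i in aln.ids) + 2
    top = aln.rows[0][a - 1:b]
    lines = [f"{aln.ids[0]:<{name_w}}{top}"]
    for rid, row in zip(aln.ids[1:], aln.rows[1:]):
        seg = row[a - 1:b]
        out = []
        for ct, cr in zip(top, seg):
            if cr == ct:
                out.append("-")
            elif cr == "-":
                out.append(GAP_GLYPH)
            else:
                out.append(cr)
        lines.append(f"{rid:<{name_w}}{''.join(out)}")
    return "\n".join(header + lines) + "\n"


@dataclass
class MotifReport:
    """Location and per-isozyme state of the ATP-binding G-X-G-X-X-G motif."""
    window_start: int | None
    match_fraction: float
    entries: list = field(default_factory=list)   # (id, isozyme, motif, deviations)

    @property
    def deviant_isozymes(self) -> set:
        return {iso for _, iso, _, dev in self.entries if dev}


def check_atp_motif(aln: Alignment, scheme) -> MotifReport:
    """Locate the kinase ATP-binding motif G-X-G-X-X-G in the alignment.

    The motif window is the 6-column gap-free stretch where the largest
    fraction (>= 50%) of rows matches G at positions 1, 3 and 6; rows
    deviating at any G position are flagged per isozyme.
    """
    arr = aln.array
    best = (0.0, None)
    for start in range(1, aln.ncols - 4):
        win = arr[:, start - 1:start + 5]
        rowfree = (win != b"-").all(axis=1)
        match = rowfree & (win[:, 0] == b"G") & (win[:, 2] == b"G") & (win[:, 5] == b"G")
        frac = match.sum() / aln.nrows
        if frac > best[0]:
            best = (float(frac), start)
    frac, start = best
    if start is None or frac < 0.5:
        logger.warning("ATP-binding motif G-X-G-X-X-G not found (best fraction %.2f)",
                       frac)
        return MotifReport(None, frac)
    report = MotifReport(start, frac)
    for rid, row in zip(aln.ids, aln.rows):
        seg = row[start - 1:start + 5]
        iso = scheme.isozyme_of.get(rid, "unknown")
        deviations = [pos + 1 for pos in (0, 2, 5)
                      if seg[pos] != "G"]
        report.entries.append((rid, iso, seg, deviations))
    return report
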