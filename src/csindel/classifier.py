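"""Closest-isozyme assignment by local alignment against a labelled
reference panel, and Table-1-style presence/absence profiling.

This is a desk-scale stand-in for a BLASTp survey of annotated
proteomes: each query is scored against every panel member with
Smith-Waterman (BLOSUM62, affine gaps 11/1, the BLASTp defaults) and
assigned to the isozyme of its best hit when the score and the margin
over the runner-up isozyme clear configurable thresholds.  The default
thresholds — score >= 40% of the query's self-score, margin >= 5% —
are heuristics, since a similarity survey offers no principled cutoff;
both are exposed as parameters.

'U' (selenocysteine) is scored as 'C': BLOSUM62 has no U column.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ISOZYMES, SequenceRecord, SeqIOError

_SCORABLE = set("ACDEFGHIKLMNPQRSTVWYXBZ")


class ClassifierError(ValueError):
    pass


def _aligner(matrix: str = "BLOSUM62", gap_open: int = 11,
             gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _prepare(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _SCORABLE - {"U"}
    if bad:
        raise ClassifierError(f"residues outside alphabet: {sorted(bad)}")
    return seq.replace("U", "C")


def smith_waterman(q: str, r: str, matrix: str = "BLOSUM62",
                   gap_open: int = 11, gap_extend: int = 1):
    """Optimal local alignment score and aligned strings under affine gaps.

    Returns ``(score, (aligned_q, aligned_r))``; the floor score for
    sequences with no positively scoring alignment is 0 with an empty
    alignment.
    """
    if not q or not r:
        raise ClassifierError("empty sequence")
    q, r = _prepare(q), _prepare(r)
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = float(aligner.score(q, r))
    if score <= 0:
        return 0.0, ("", "")
    aln = aligner.align(q, r)[0]
    return score, (str(aln[0]), str(aln[1]))


@dataclass
class AssignmentResult:
    query_id: str
    best_isozyme: str
    best_score: float
    runner_up: str
    margin: float
    verdict: str                 # confident | ambiguous | no_hit
    taxon_group: str = "other"
    species: str = ""


def assign_isozyme(query: SequenceRecord, panel, s_min: float | None = None,
                   m_min: float | None = None, matrix: str = "BLOSUM62",
                   gap_open: int = 11, gap_extend: int = 1) -> AssignmentResult:
    """Assign a query protein to its closest isozyme in the panel.

    ``s_min``/``m_min`` default to 40% and 5% of the query self-score.
    """
    panel = list(panel)
    if not panel:
        raise ClassifierError("empty reference panel")
    isozymes = {p.isozyme for p in panel if p.isozyme != "unknown"}
    if len(isozymes) < 2:
        raise ClassifierError("panel must cover >= 2 isozymes")
    self_score, _ = smith_waterman(query.residues, query.residues,
                                   matrix, gap_open, gap_extend)
    if s_min is None:
        s_min = 0.40 * self_score
    if m_min is None:
        m_min = 0.05 * self_score
    best_per_iso: dict[str, float] = {}
    for p in panel:
        if p.isozyme == "unknown":
            continue
        score, _ = smith_waterman(query.residues, p.residues,
                                  matrix, gap_open, gap_extend)
        if score > best_per_iso.get(p.isozyme, -1.0):
            best_per_iso[p.isozyme] = score
    ranked = sorted(best_per_iso.items(), key=lambda kv: (-kv[1], kv[0]))
    best_iso, best = ranked[0]
    runner_iso, runner = ranked[1]
    margin = best - runner
    if best < s_min:
        verdict = "no_hit"
    elif margin < m_min:
        verdict = "ambiguous"
    else:
        verdict = "confident"
    return AssignmentResult(query.id, best_iso, best, runner_iso, margin,
                            verdict, query.taxon_group, query.species)


@dataclass
class PresenceAbsenceMatrix:
    """Taxon groups x isozymes with '+', '-' or '+/-' cells."""
    table: pd.DataFrame

    def cell(self, group: str, isozyme: str) -> str:
        return self.table.loc[group, isozyme]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def build_matrix(assignments, isozymes=ISOZYMES) -> PresenceAbsenceMatrix:
    """Presence/absence matrix over taxon groups.

    '+'  : every surveyed species in the group has a confident
           assignment for the isozyme;
    '+/-': some but not all species do;
    '-'  : none do.
    """
    rows = []
    for a in assignments:
        if not a.taxon_group or a.taxon_group == "unknown":
            raise ClassifierError(f"query {a.query_id!r} has no taxon group")
        rows.append((a.taxon_group, a.species or a.query_id,
                     a.best_isozyme, a.verdict))
    df = pd.DataFrame(rows, columns=["group", "species", "isozyme", "verdict"])
    groups = sorted(df["group"].unique())
    out = pd.DataFrame("-", index=groups, columns=list(isozymes))
    for grp, sub in df.groupby("group"):
        species = set(sub["species"])
        for iso in isozymes:
            hit = sub[(sub["isozyme"] == iso) & (sub["verdict"] == "confident")]
            covered = set(hit["species"])
            if covered == species and species:
                out.loc[grp, iso] = "+"
            elif covered:
                out.loc[grp, iso] = "+/-"
    return PresenceAbsenceMatrix(out)


def assignments_to_tsv(assignments, path) -> None:
    pd.DataFrame([vars(a) for a in assignments]).to_csv(path, sep="\t",
                                                        index=False)
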