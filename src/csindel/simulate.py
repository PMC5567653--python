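"""Sequence-family simulator with planted clade-specific indels.

A protein family is evolved along a known guide tree under the JTT
model (exact continuous-time simulation per site, so realised
substitution counts are available per branch).  Clade-specific indels
are then planted deterministically on the stem of their clade and
inherited by every descendant — the generative assumption behind
conserved signature indels (a rare genetic change in a common ancestor,
vertically inherited).  Planting is post hoc rather than via a
stochastic indel process: the scanner benchmark needs exact ground
truth, not indel-model realism.

Draw order (stable across runs for a fixed seed): root core sequence,
core evolution in preorder, insert segments in listed order (segment
root sequence then subtree evolution), decoy flank scrambles in listed
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import jtt
from .alignment import Alignment
from .seqio import GroupScheme
from .tree import Tree, mrca


class SimulationError(ValueError):
    pass


@dataclass
class InsertSpec:
    """Insert planted before core column ``anchor``.

    ``segments`` is a list of (clade_label, length): the block is their
    concatenation, each segment carried only by its clade (nested
    segments model clade-internal length variation, e.g. a secondary
    expansion in a subclade).
    """
    name: str
    anchor: int
    segments: list
    flank: int = 5


@dataclass
class DeleteSpec:
    """Deletion of existing core columns starting at ``start``.

    ``variants``: (clade_label, length) pairs sharing the same start
    column; different lengths in different clades model paired-length
    loci."""
    name: str
    start: int
    variants: list
    flank: int = 5

    @property
    def width(self) -> int:
        return max(ln for _, ln in self.variants)


@dataclass
class DecoySpec:
    """A non-signature gap run planted in a single row (alignment noise).

    With ``scramble_flanks`` the surrounding columns are replaced by
    i.i.d. equilibrium draws, destroying flank conservation."""
    row: str
    start: int
    length: int
    scramble_flanks: bool = False
    scramble_halfwidth: int = 30


@dataclass
class SimulationConfig:
    guide_tree: str
    root_length: int
    clades: dict = field(default_factory=dict)       # label -> leaf names
    conserved_columns: set = field(default_factory=set)
    fixed_columns: dict = field(default_factory=dict)  # core col -> residue
    overrides: list = field(default_factory=list)      # (leaf, core col, residue)
    inserts: list = field(default_factory=list)
    deletions: list = field(default_factory=list)
    decoys: list = field(default_factory=list)
    seed: int = 42
    leaf_isozymes: dict = field(default_factory=dict)
    leaf_taxon_groups: dict = field(default_factory=dict)


@dataclass
class TruthEntry:
    name: str
    kind: str                    # insert | delete
    start: int                   # final alignment columns, closed interval
    end: int
    clades: dict                 # clade label -> planted length


@dataclass
class TruthTable:
    entries: list = field(default_factory=list)
    decoys: list = field(default_factory=list)      # (row, start, end) final coords

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("name\tkind\tstart\tend\tclades\n")
            for e in self.entries:
                clades = ",".join(f"{c}:{l}" for c, l in sorted(e.clades.items()))
                fh.write(f"{e.name}\t{e.kind}\t{e.start}\t{e.end}\t{clades}\n")


@dataclass
class SimulationResult:
    alignment: Alignment
    scheme: GroupScheme
    truth: TruthTable
    branch_substitutions: list = field(default_factory=list)  # (label, t, count)
    config: SimulationConfig | None = None
    guide_tree: Tree | None = None

    def __iter__(self):
        return iter((self.alignment, self.scheme, self.truth))


# -- CTMC machinery ------------------------------------------------------

def _jump_tables():
    Q = jtt.rate_matrix()
    rates = -np.diag(Q)
    jump = Q / rates[:, None]
    np.fill_diagonal(jump, 0.0)
    return rates, np.cumsum(jump, axis=1)


def _evolve_branch(state: np.ndarray, t: float, mutable: np.ndarray,
                   rng: np.random.Generator, rates, cumjump) -> tuple:
    """Exact per-site Gillespie simulation along one branch.

    Returns (child state, number of realised substitution events)."""
    out = state.copy()
    remaining = np.where(mutable, t, 0.0)
    active = np.flatnonzero(remaining > 0)
    count = 0
    while active.size:
        wait = rng.exponential(1.0 / rates[out[active]])
        jumped = wait < remaining[active]
        idx = active[jumped]
        remaining[idx] -= wait[jumped]
        if idx.size:
            u = rng.random(idx.size)
            out[idx] = (cumjump[out[idx]] < u[:, None]).sum(axis=1)
            count += idx.size
        active = idx
    return out, count


def _draw_root(rng: np.random.Generator, length: int) -> np.ndarray:
    pi = jtt.equilibrium_frequencies()
    return rng.choice(20, size=length, p=pi)


def _simulate_on_tree(tree: Tree, root_state: np.ndarray, mutable: np.ndarray,
                      rng: np.random.Generator) -> tuple[dict, list]:
    """Evolve a state vector down a tree; returns leaf states and
    per-branch (label, t, substitution count)."""
    rates, cumjump = _jump_tables()
    leaves: dict[str, np.ndarray] = {}
    branch_counts: list = []

    def descend(node, state):
        for ch in node.children:
            t = ch.length or 0.0
            child_state, nsub = _evolve_branch(state, t, mutable, rng,
                                               rates, cumjump)
            label = ch.name or f"internal@{min(ch.leaf_names())}"
            branch_counts.append((label, t, nsub))
            if ch.is_leaf:
                leaves[ch.name] = child_state
            else:
                descend(ch, child_state)

    descend(tree.root, root_state)
    return leaves, branch_counts


# -- validation ----------------------------------------------------------

def _mask_columns(cfg: SimulationConfig) -> set:
    cols = set(int(c) for c in cfg.conserved_columns)
    for ins in cfg.inserts:
        a, f = ins.anchor, ins.flank
        cols.update(range(max(1, a - f), a))
        cols.update(range(a, min(cfg.root_length, a + f - 1) + 1))
    for de in cfg.deletions:
        end = de.start + de.width - 1
        cols.update(range(max(1, de.start - de.flank), de.start))
        cols.update(range(end + 1, min(cfg.root_length, end + de.flank) + 1))
    return cols


def _validate(cfg: SimulationConfig, tree: Tree) -> None:
    leaf_names = tree.leaf_names()
    for label, members in cfg.clades.items():
        members = set(members)
        if not members <= leaf_names:
            raise SimulationError(f"clade {label!r}: leaves missing from tree")
        node = mrca(tree, members)
        if node.leaf_names() != frozenset(members):
            raise SimulationError(f"clade {label!r} is not monophyletic in the guide tree")
    L = cfg.root_length

    def clade(label):
        if label not in cfg.clades:
            raise SimulationError(f"unknown clade label {label!r}")

    intervals = []
    for ins in cfg.inserts:
        if not 2 <= ins.anchor <= L:
            raise SimulationError(f"{ins.name}: anchor {ins.anchor} out of range")
        for lab, ln in ins.segments:
            clade(lab)
            if ln < 1:
                raise SimulationError(f"{ins.name}: segment length {ln} < 1")
        intervals.append((ins.anchor - 1, ins.anchor, ins.flank, ins.name))
    occupied: set[int] = set()
    for de in cfg.deletions:
        end = de.start + de.width - 1
        if not (2 <= de.start and end <= L - 1):
            raise SimulationError(f"{de.name}: interval [{de.start},{end}] out of range")
        for lab, ln in de.variants:
            clade(lab)
            if ln < 1:
                raise SimulationError(f"{de.name}: variant length {ln} < 1")
        intervals.append((de.start, end, de.flank, de.name))
        occupied.update(range(de.start, end + 1))
    intervals.sort()
    for (s1, e1, f1, n1), (s2, e2, f2, n2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise SimulationError(f"planted loci {n1} and {n2} overlap")
        if s2 - e1 - 1 < max(f1, f2):
            raise SimulationError(
                f"planted loci {n1} and {n2} closer than their flank masks")
    mask = _mask_columns(cfg)
    if occupied & mask:
        raise SimulationError("a deletion overlaps a conserved flank mask")
    for col in cfg.fixed_columns:
        if col in occupied:
            raise SimulationError(f"fixed column {col} inside a deletion")
    seen: set[int] = set()
    for dc in cfg.decoys:
        if dc.row not in leaf_names:
            raise SimulationError(f"decoy row {dc.row!r} not in tree")
        cols = set(range(dc.start, dc.start + dc.length))
        if dc.start < 2 or dc.start + dc.length - 1 > L - 1:
            raise SimulationError("decoy run touches an alignment terminus")
        if cols & (mask | occupied | set(cfg.fixed_columns) | seen):
            raise SimulationError(
                f"decoy at {dc.start} collides with a locus, mask or decoy")
        seen |= cols


# -- main entry points ---------------------------------------------------

def simulate_family(cfg: SimulationConfig) -> SimulationResult:
    """Evolve the family and plant the configured indels.

    Reproducible per seed; the emitted alignment is column-consistent
    (insert blocks open gap columns in every non-carrier row).
    """
    tree = Tree.from_newick(cfg.guide_tree)
    _validate(cfg, tree)
    rng = np.random.default_rng(cfg.seed)
    L = cfg.root_length
    mask_cols = _mask_columns(cfg)
    mutable = np.ones(L, dtype=bool)
    for c in mask_cols:
        mutable[c - 1] = False
    root = _draw_root(rng, L)
    for col, res in cfg.fixed_columns.items():
        root[col - 1] = jtt.AA_INDEX[res]
        mutable[col - 1] = False
    leaf_states, branch_counts = _simulate_on_tree(tree, root, mutable, rng)
    leaf_order = [n.name for n in tree.leaves()]
    core = {name: leaf_states[name].copy() for name in leaf_order}

    # insert blocks: {anchor core col: list of (spec, columns dict)}
    blocks: list = []
    for ins in cfg.inserts:
        seg_cols = []          # list of (carrier leaf set, {leaf: codes})
        for lab, ln in ins.segments:
            members = frozenset(cfg.clades[lab])
            sub = mrca(tree, members)
            seg_root = _draw_root(rng, ln)
            subtree = Tree(sub)
            states, _ = _simulate_on_tree(subtree, seg_root,
                                          np.ones(ln, dtype=bool), rng)
            if sub.is_leaf:
                states = {sub.name: seg_root}
            seg_cols.append((members, ln, states))
        blocks.append((ins, seg_cols))

    # deletions (on core columns)
    GAP = -1
    for de in cfg.deletions:
        for lab, ln in de.variants:
            for leaf in cfg.clades[lab]:
                core[leaf][de.start - 1:de.start - 1 + ln] = GAP

    # decoys
    pi = jtt.equilibrium_frequencies()
    for dc in cfg.decoys:
        core[dc.row][dc.start - 1:dc.start - 1 + dc.length] = GAP
        if dc.scramble_flanks:
            lo = max(1, dc.start - dc.scramble_halfwidth)
            hi = min(L, dc.start + dc.length - 1 + dc.scramble_halfwidth)
            for col in range(lo, hi + 1):
                if (col in mask_cols or col in cfg.fixed_columns
                        or dc.start <= col < dc.start + dc.length):
                    continue
                draws = rng.choice(20, size=len(leaf_order), p=pi)
                for leaf, val in zip(leaf_order, draws):
                    core[leaf][col - 1] = val

    for leaf, col, res in cfg.overrides:
        core[leaf][col - 1] = jtt.AA_INDEX[res]

    # assemble final columns: insert blocks precede their anchor column
    blocks_at: dict[int, list] = {}
    for ins, seg_cols in blocks:
        blocks_at.setdefault(ins.anchor, []).append((ins, seg_cols))
    rows = {leaf: [] for leaf in leaf_order}
    truth = TruthTable()
    pos = 0
    core_final: dict[int, int] = {}
    for c in range(1, L + 1):
        for ins, seg_cols in blocks_at.get(c, []):
            start = pos + 1
            clade_lengths: dict[str, int] = {}
            for (members, ln, states), (lab, _) in zip(seg_cols, ins.segments):
                for k in range(ln):
                    pos += 1
                    for leaf in leaf_order:
                        if leaf in members:
                            rows[leaf].append(int(states[leaf][k]))
                        else:
                            rows[leaf].append(GAP)
                clade_lengths[lab] = ln
            truth.entries.append(TruthEntry(ins.name, "insert", start, pos,
                                            clade_lengths))
        pos += 1
        core_final[c] = pos
        for leaf in leaf_order:
            rows[leaf].append(int(core[leaf][c - 1]))
    for de in cfg.deletions:
        truth.entries.append(TruthEntry(
            de.name, "delete", core_final[de.start],
            core_final[de.start + de.width - 1],
            {lab: ln for lab, ln in de.variants}))
    for dc in cfg.decoys:
        truth.decoys.append((dc.row, core_final[dc.start],
                             core_final[dc.start + dc.length - 1]))
    truth.entries.sort(key=lambda e: e.start)

    alpha = jtt.AA_ORDER
    str_rows = ["".join("-" if v == GAP else alpha[v] for v in rows[leaf])
                for leaf in leaf_order]
    aln = Alignment(ids=list(leaf_order), rows=str_rows)

    scheme = GroupScheme()
    for leaf in leaf_order:
        scheme.isozyme_of[leaf] = cfg.leaf_isozymes.get(leaf, "unknown")
        if leaf in cfg.leaf_taxon_groups:
            scheme.taxon_group_of[leaf] = cfg.leaf_taxon_groups[leaf]
    scheme.custom_groups = {lab: set(mem) for lab, mem in cfg.clades.items()}
    return SimulationResult(aln, scheme, truth, branch_counts, cfg, tree)


def evolve_sequence(residues: str, t: float, rng: np.random.Generator) -> str:
    """Mutate an ungapped protein sequence for time t under JTT
    (transition-matrix sampling; used to make classifier queries)."""
    P = jtt.transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    codes = jtt.encode(residues)
    if (codes < 0).any():
        raise SimulationError("sequence must be gap-free canonical residues")
    u = rng.random(len(codes))
    out = (cum[codes] < u[:, None]).sum(axis=1)
    return "".join(jtt.AA_ORDER[v] for v in out)


def benchmark_calls(calls, truth: TruthTable, tol: int = 3):
    """Precision/recall of scanner calls against the planted truth.

    A call matches a truth locus when their column hulls overlap after
    expanding the truth interval by ``tol`` columns (signature positions
    may legitimately shift by a few residues)."""
    matched_truth = set()
    matched_calls = 0
    for call in calls:
        hit = False
        for k, e in enumerate(truth.entries):
            if call.locus.start <= e.end + tol and call.locus.end >= e.start - tol:
                matched_truth.add(k)
                hit = True
        if hit:
            matched_calls += 1
    precision = matched_calls / len(calls) if calls else 1.0
    recall = len(matched_truth) / len(truth.entries) if truth.entries else 1.0
    return precision, recall
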