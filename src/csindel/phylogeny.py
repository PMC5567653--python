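"""Catalytic-domain phylogeny: JTT pairwise maximum-likelihood
distances, neighbour joining, column bootstrap, midpoint rooting,
monophyly reporting and a pruning log-likelihood for fixed topologies.

The published analysis used a full ML tree search; at desk scale the
reproducible surface is topology-level (class clusters, polyphyly,
rooting order), which JTT-distance NJ recovers deterministically.  The
pairwise distance between two rows is the t maximising
prod_cols pi_a P_ab(t) under the JTT model with pairwise gap deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import jtt
from .alignment import Alignment
from .tree import Node, Tree, TreeError, mrca

T_MAX = 10.0
_GRID = np.concatenate([[1e-6], np.geomspace(1e-4, T_MAX, 160)])


class PhylogenyError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise PhylogenyError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise PhylogenyError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise PhylogenyError("negative distances")
        self.values = v

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids,
                     columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.values)


def _pair_counts(e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """20x20 substitution count matrix over shared canonical columns."""
    ok = (e1 >= 0) & (e2 >= 0)
    if not ok.any():
        raise PhylogenyError("no shared non-gap columns between rows")
    return np.bincount(e1[ok] * 20 + e2[ok], minlength=400).reshape(20, 20)


def _log_transition_grid() -> np.ndarray:
    """log P(t) on the fixed refinement grid, flattened to (G, 400)."""
    P = jtt.transition_matrices(_GRID)
    return np.log(np.clip(P, 1e-300, None)).reshape(len(_GRID), 400)


_LOGP_GRID_CACHE: list = []


def _logp_grid() -> np.ndarray:
    if not _LOGP_GRID_CACHE:
        _LOGP_GRID_CACHE.append(_log_transition_grid())
    return _LOGP_GRID_CACHE[0]


def jtt_distance(row1: str, row2: str, t_max: float = T_MAX) -> float:
    """Pairwise ML distance (expected substitutions/site) under JTT.

    Bounded scalar optimisation of the pairwise likelihood; identical
    rows give 0.0; saturated pairs are capped at ``t_max`` with a
    warning.
    """
    e1, e2 = jtt.encode(row1), jtt.encode(row2)
    N = _pair_counts(e1, e2)
    if np.trace(N) == N.sum():
        return 0.0
    flat = N.reshape(-1).astype(float)
    ll = _logp_grid() @ flat
    k = int(np.argmax(ll))
    lo = _GRID[max(k - 1, 0)]
    hi = _GRID[min(k + 1, len(_GRID) - 1)]

    def nll(t: float) -> float:
        P = jtt.transition_matrix(t)
        return -float(flat @ np.log(np.clip(P.reshape(-1), 1e-300, None)))

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    t_hat = float(res.x)
    if t_hat >= t_max * 0.999:
        warnings.warn("saturated pair: distance capped at "
                      f"{t_max}", RuntimeWarning, stacklevel=2)
        return t_max
    return t_hat


def _distances_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised ML distances for many pairs at once.

    ``counts``: (npairs, 400) substitution counts.  Grid argmax with a
    parabolic refinement in log-t; identical pairs return 0.
    """
    ll = counts @ _logp_grid().T                  # (npairs, G)
    k = np.argmax(ll, axis=1)
    km = np.clip(k - 1, 0, len(_GRID) - 1)
    kp = np.clip(k + 1, 0, len(_GRID) - 1)
    x0, x1, x2 = np.log(_GRID[km]), np.log(_GRID[k]), np.log(_GRID[kp])
    y0 = np.take_along_axis(ll, km[:, None], 1)[:, 0]
    y1 = np.take_along_axis(ll, k[:, None], 1)[:, 0]
    y2 = np.take_along_axis(ll, kp[:, None], 1)[:, 0]
    denom = (y0 - 2 * y1 + y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (y0 - y2) / denom
    shift = np.where(np.isfinite(shift), np.clip(shift, -1.0, 1.0), 0.0)
    step = np.where(kp > km, (x2 - x0) / 2.0, 0.0)
    t = np.exp(x1 + shift * step)
    ident = np.einsum("pi->p", counts.reshape(-1, 20, 20)[:, np.arange(20), np.arange(20)])
    total = counts.sum(axis=1)
    t = np.where(ident == total, 0.0, np.minimum(t, T_MAX))
    return t


def jtt_distance_matrix(aln: Alignment) -> DistanceMatrix:
    enc = np.stack([jtt.encode(r) for r in aln.rows])
    n = aln.nrows
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = np.zeros((len(pairs), 400))
    for p, (i, j) in enumerate(pairs):
        counts[p] = _pair_counts(enc[i], enc[j]).reshape(-1)
    t = _distances_from_counts(counts)
    D = np.zeros((n, n))
    for p, (i, j) in enumerate(pairs):
        D[i, j] = D[j, i] = t[p]
    return DistanceMatrix(list(aln.ids), D)


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining.

    Q-criterion ties break on the lowest index pair; negative branch
    lengths are clamped to zero.  The result is unrooted (trifurcating
    root node) with no supports.
    """
    n = len(D.ids)
    if n < 3:
        raise PhylogenyError(f"neighbour joining needs >= 3 taxa, got {n}")
    d = D.values.copy()
    nodes = [Node(name=i) for i in D.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        k = int(np.argmin(q))                  # row-major: lowest index pair on ties
        ai, aj = divmod(k, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.add(nodes[i])
        parent.add(nodes[j])
        # new distances
        new = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        for col, a in enumerate(active):
            d[-1, a] = d[a, -1] = max(new[col], 0.0)
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # join the final three on one internal node
    root = Node()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].length = max(ln, 0.0)
            root.add(nodes[idx])
    else:                                      # pragma: no cover
        raise PhylogenyError("unexpected NJ state")
    return Tree(root)


def bootstrap_supports(aln: Alignment, n_reps: int = 100,
                       seed: int = 42) -> Tree:
    """Column bootstrap on a gap-free alignment.

    Supports (percent of replicates containing each internal bipartition
    of the point-estimate tree) are attached to the point tree, which is
    returned unrooted.
    """
    if n_reps < 1:
        raise PhylogenyError("n_reps must be >= 1")
    if any("-" in row for row in aln.rows):
        raise PhylogenyError("bootstrap requires a gap-free alignment; "
                             "run strip_gap_columns first")
    rng = np.random.default_rng(seed)
    enc = np.stack([jtt.encode(r) for r in aln.rows])
    n, L = enc.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pair_codes = np.stack([enc[i] * 20 + enc[j] for i, j in pairs])  # (P, L)
    npairs = len(pairs)
    offsets = np.arange(npairs)[:, None] * 400

    def matrix_from_cols(cols) -> DistanceMatrix:
        codes = pair_codes[:, cols]
        counts = np.bincount((codes + offsets).reshape(-1),
                             minlength=npairs * 400).reshape(npairs, 400)
        t = _distances_from_counts(counts.astype(float))
        D = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            D[i, j] = D[j, i] = t[p]
        return DistanceMatrix(list(aln.ids), D)

    point = nj_tree(matrix_from_cols(np.arange(L)))
    target = point.bipartitions()
    hits = {key: 0 for key in target}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(matrix_from_cols(cols))
        found = rep.bipartitions()
        for key in hits:
            if key in found:
                hits[key] += 1
    for key, node in target.items():
        node.support = int(round(100.0 * hits[key] / n_reps))
    return point


@dataclass
class MonophylyReport:
    entries: dict    # label -> dict(monophyletic, support, offending)

    def monophyletic(self, label: str) -> bool:
        return self.entries[label]["monophyletic"]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label\tmonophyletic\tsupport\toffending_leaves\n")
            for lab in sorted(self.entries):
                e = self.entries[lab]
                sup = "" if e["support"] is None else e["support"]
                off = ",".join(sorted(e["offending"]))
                fh.write(f"{lab}\t{e['monophyletic']}\t{sup}\t{off}\n")


def monophyly(tree: Tree, scheme, grouping: str = "by_class") -> MonophylyReport:
    """Per-label monophyly on the (un)rooted tree.

    A label is monophyletic when its leaf set is one side of a
    bipartition (single-leaf labels trivially so).  Otherwise the
    offending leaves are the extras under the smallest clade containing
    the label.
    """
    names = [n.name for n in tree.leaves()]
    groups = scheme.groups(grouping, names)
    labeled = {i for mem in groups.values() for i in mem}
    missing = set(names) - labeled
    if missing:
        raise TreeError(f"unlabeled leaves: {sorted(missing)[:5]}")
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    bip = tree.bipartitions()
    entries = {}
    for lab, members in groups.items():
        mset = frozenset(members)
        if len(mset) == 1 or len(all_leaves - mset) <= 1:
            entries[lab] = {"monophyletic": True, "support": None, "offending": set()}
            continue
        key = frozenset(all_leaves - mset) if anchor in mset else mset
        node = bip.get(key)
        if node is not None or mset == all_leaves:
            if node is None:        # label covers the whole tree
                node = tree.root
            entries[lab] = {"monophyletic": True,
                            "support": node.support, "offending": set()}
        else:
            clade = mrca(tree, mset)
            entries[lab] = {"monophyletic": False, "support": None,
                            "offending": set(clade.leaf_names()) - mset}
    return MonophylyReport(entries)


def outlying_clades(rooted: Tree, n: int = 2) -> list:
    """Leaf-name sets of the basal-most clades of a rooted tree.

    Peels the smaller side off the root split, then off the remaining
    side, ``n`` times — the clades a reader would call 'most outlying'.
    """
    out = []
    node = rooted.root
    for _ in range(n):
        if node.is_leaf or len(node.children) < 2:
            break
        sides = sorted(node.children, key=lambda c: (len(c.leaf_names()),
                                                     min(c.leaf_names())))
        out.append(sides[0].leaf_names())
        node = sides[-1]
    return out


def bootstrap_bipartition_frequency(aln: Alignment, leafset, n_reps: int = 100,
                                    seed: int = 42) -> float:
    """Percent of bootstrap replicates whose NJ tree contains the given
    split (e.g. how often two classes associate), whether or not the
    point-estimate tree does."""
    if any("-" in row for row in aln.rows):
        raise PhylogenyError("bootstrap requires a gap-free alignment")
    rng = np.random.default_rng(seed)
    enc = np.stack([jtt.encode(r) for r in aln.rows])
    nrow, L = enc.shape
    pairs = [(i, j) for i in range(nrow) for j in range(i + 1, nrow)]
    pair_codes = np.stack([enc[i] * 20 + enc[j] for i, j in pairs])
    offsets = np.arange(len(pairs))[:, None] * 400
    all_leaves = frozenset(aln.ids)
    anchor = min(all_leaves)
    leafset = frozenset(leafset)
    key = all_leaves - leafset if anchor in leafset else leafset
    hits = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        codes = pair_codes[:, cols]
        counts = np.bincount((codes + offsets).reshape(-1),
                             minlength=len(pairs) * 400).reshape(len(pairs), 400)
        t = _distances_from_counts(counts.astype(float))
        D = np.zeros((nrow, nrow))
        for p, (i, j) in enumerate(pairs):
            D[i, j] = D[j, i] = t[p]
        rep = nj_tree(DistanceMatrix(list(aln.ids), D))
        if key in rep.bipartitions():
            hits += 1
    return 100.0 * hits / n_reps


def tree_log_likelihood(aln: Alignment, tree: Tree, model=None) -> float:
    """Felsenstein pruning log-likelihood of a gap-free alignment on a
    tree with branch lengths (JTT, no rate heterogeneity)."""
    if set(n.name for n in tree.leaves()) != set(aln.ids):
        raise PhylogenyError("tree leaves do not match alignment ids")
    if any("-" in row for row in aln.rows):
        raise PhylogenyError("likelihood requires a gap-free alignment")
    enc = {rid: jtt.encode(row) for rid, row in zip(aln.ids, aln.rows)}
    L = aln.ncols
    pi = jtt.equilibrium_frequencies()

    def partial(node: Node) -> np.ndarray:
        if node.is_leaf:
            p = np.zeros((20, L))
            e = enc[node.name]
            known = e >= 0
            p[:, ~known] = 1.0
            p[e[known], np.flatnonzero(known)] = 1.0
            return p
        out = np.ones((20, L))
        for ch in node.children:
            P = jtt.transition_matrix(ch.length or 0.0)
            out *= P @ partial(ch)
        return out

    site = pi @ partial(tree.root)
    return float(np.sum(np.log(np.clip(site, 1e-300, None))))
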