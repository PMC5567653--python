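import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from csindel import jtt
from csindel.alignment import Alignment
from csindel.phylogeny import (DistanceMatrix, PhylogenyError,
                               bootstrap_supports, jtt_distance,
                               jtt_distance_matrix, monophyly, nj_tree,
                               outlying_clades, tree_log_likelihood)
from csindel.seqio import GroupScheme
from csindel.tree import Tree, TreeError, midpoint_root


class TestJttModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        Q = jtt.rate_matrix()
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_detailed_balance(self):
        Q = jtt.rate_matrix()
        pi = jtt.equilibrium_frequencies()
        flow = pi[:, None] * Q
        assert np.allclose(flow, flow.T, atol=1e-12)

    def test_frequencies_sum_to_one(self):
        assert jtt.equilibrium_frequencies().sum() == pytest.approx(1.0)

    def test_unit_expected_rate(self):
        Q = jtt.rate_matrix()
        pi = jtt.equilibrium_frequencies()
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_exchangeability_checksum(self):
        # guards the transcription of the 190 published integers
        assert jtt.matrix_checksum() == 18873

    def test_transition_matrix_stochastic_and_matches_expm(self):
        for t in (0.01, 0.3, 2.0):
            P = jtt.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.allclose(P, expm(jtt.rate_matrix() * t), atol=1e-10)


def sample_pair(t, length, seed):
    """Two sequences separated by time t under JTT."""
    rng = np.random.default_rng(seed)
    pi = jtt.equilibrium_frequencies()
    anc = rng.choice(20, size=length, p=pi)
    P = jtt.transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    der = (cum[anc] < u[:, None]).sum(axis=1)
    alpha = jtt.AA_ORDER
    return ("".join(alpha[i] for i in anc), "".join(alpha[i] for i in der))


class TestJttDistance:
    def test_identical_rows_give_zero(self):
        assert jtt_distance("ACDEF", "ACDEF") == 0.0

    def test_symmetry(self):
        a, b = sample_pair(0.4, 300, 5)
        assert jtt_distance(a, b) == pytest.approx(jtt_distance(b, a), abs=1e-6)

    def test_no_shared_columns_errors(self):
        with pytest.raises(PhylogenyError):
            jtt_distance("A-", "-A")

    def test_recovers_simulated_divergence(self):
        for seed in range(3):
            a, b = sample_pair(0.1, 10_000, seed)
            assert jtt_distance(a, b) == pytest.approx(0.1, abs=0.02)

    def test_consistency_bias_shrinks_with_length(self):
        errs = {}
        for L in (1_000, 10_000):
            e = [abs(jtt_distance(*sample_pair(0.1, L, s)) - 0.1)
                 for s in range(8)]
            errs[L] = np.mean(e)
        assert errs[10_000] < errs[1_000]

    def test_matrix_agrees_with_scalar_optimiser(self):
        base, _ = sample_pair(0.0, 400, 0)
        rows = []
        rng_seeds = range(4)
        from csindel.simulate import evolve_sequence
        for s in rng_seeds:
            rng = np.random.default_rng(100 + s)
            rows.append(evolve_sequence(base, 0.3, rng))
        aln = Alignment(ids=list("abcd"), rows=rows)
        D = jtt_distance_matrix(aln)
        for i, j in itertools.combinations(range(4), 2):
            expect = jtt_distance(rows[i], rows[j])
            assert D.values[i, j] == pytest.approx(expect, rel=0.02, abs=1e-3)


def four_taxon_matrix(la, lb, lc, ld, internal):
    ids = list("ABCD")
    d = np.zeros((4, 4))
    depths = dict(A=la, B=lb, C=lc, D=ld)
    for i, j in itertools.combinations(range(4), 2):
        a, b = ids[i], ids[j]
        same = {a, b} in ({"A", "B"}, {"C", "D"})
        d[i, j] = d[j, i] = depths[a] + depths[b] + (0 if same else internal)
    return DistanceMatrix(ids, d)


def brute_force_best_topology(D):
    """Least-squares fit of all three unrooted 4-taxon topologies."""
    ids = D.ids
    best = None
    for split in (("A", "B"), ("A", "C"), ("A", "D")):
        left = set(split)
        # four-point condition residual for this pairing
        others = [i for i in ids if i not in left]
        a, b = sorted(left)
        c, dd = sorted(others)
        g = lambda x, y: D.values[ids.index(x), ids.index(y)]
        resid = abs((g(a, c) + g(b, dd)) - (g(a, dd) + g(b, c)))
        internal = 0.5 * (g(a, c) + g(b, dd) - g(a, b) - g(c, dd))
        if best is None or (resid, -internal) < best[0]:
            best = ((resid, -internal), frozenset(left))
    return best[1]


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        D = four_taxon_matrix(1, 2, 3, 4, internal=1)
        tree = nj_tree(D)
        assert frozenset({"C", "D"}) in tree.bipartitions() or \
               frozenset({"A", "B"}) in tree.bipartitions()
        # branch lengths recovered exactly
        lengths = {n.name: n.length for n in tree.root.walk() if n.is_leaf}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        assert brute_force_best_topology(D) == frozenset({"A", "B"})

    def test_random_additive_matrices_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            la, lb, lc, ld = rng.uniform(0.5, 3, size=4)
            internal = rng.uniform(0.3, 2)
            D = four_taxon_matrix(la, lb, lc, ld, internal)
            tree = nj_tree(D)
            split = brute_force_best_topology(D)
            keys = tree.bipartitions()
            complement = frozenset(D.ids) - split
            assert split in keys or complement in keys

    def test_agrees_with_skbio_on_random_additive_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(2)
        for trial in range(5):
            tree = random_tree(rng, nleaves=8)
            paths = tree.leaf_path_lengths()
            ids = sorted(tree.leaf_names())
            n = len(ids)
            d = np.zeros((n, n))
            for (a, b), dist in paths.items():
                i, j = ids.index(a), ids.index(b)
                d[i, j] = d[j, i] = dist
            sk_tree = sk_nj(skbio.DistanceMatrix(d, ids))
            my_tree = nj_tree(DistanceMatrix(ids, d))
            sk_splits = set()
            anchor = min(ids)
            for node in sk_tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    sk_splits.add(frozenset(ids) - side if anchor in side else side)
            assert set(my_tree.bipartitions()) == sk_splits

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(list("ABC"),
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.]]))
        tree = nj_tree(D)
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(PhylogenyError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.]])))


class TestBootstrap:
    def test_unambiguous_signal_gives_full_support(self):
        # identical rows within clusters, consistent differences between
        # them: no resample can produce a conflicting bipartition
        rows = {"a1": "AAAAAAAAAACCCCC", "a2": "AAAAAAAAAACCCCC",
                "b1": "AAAAAAAAAAGGGGG", "b2": "AAAAAAAAAAGGGGG"}
        aln = Alignment(ids=list(rows), rows=list(rows.values()))
        tree = bootstrap_supports(aln, n_reps=25, seed=0)
        sups = [n.support for n in tree.root.walk()
                if n.support is not None]
        assert sups and all(s == 100 for s in sups)

    def test_seed_reproducibility(self, dgk):
        from csindel.alignment import strip_gap_columns
        core, _ = strip_gap_columns(dgk.alignment)
        t1 = bootstrap_supports(core, n_reps=10, seed=3)
        t2 = bootstrap_supports(core, n_reps=10, seed=3)
        assert t1.newick() == t2.newick()
        sups = [n.support for n in t1.root.walk() if n.support is not None]
        assert all(0 <= s <= 100 for s in sups)

    def test_gapped_alignment_rejected(self):
        aln = Alignment(ids=["a", "b", "c"], rows=["A-A", "AAA", "ACA"])
        with pytest.raises(PhylogenyError):
            bootstrap_supports(aln, 5, 0)


class TestMidpointRoot:
    def test_two_leaves(self):
        tree = Tree.from_newick("(a:0.5,b:1.5);")
        rooted = midpoint_root(tree)
        lengths = sorted(c.length for c in rooted.root.children)
        assert lengths == pytest.approx([0.5, 1.0])

    def test_all_zero_lengths_error(self):
        tree = Tree.from_newick("(a:0,b:0,c:0);")
        with pytest.raises(TreeError):
            midpoint_root(tree)

    def test_minimises_max_depth_on_random_trees(self):
        nx = pytest.importorskip("networkx")
        from csindel.tree import max_depth
        rng = np.random.default_rng(9)
        for trial in range(10):
            tree = random_tree(rng, nleaves=10)
            rooted = midpoint_root(tree)
            # depth of midpoint root equals half the tree diameter,
            # diameter computed independently with networkx
            g = nx.Graph()
            for p, c in tree.edges():
                g.add_edge(id(p), id(c), weight=c.length or 0.0)
            leaves = [id(n) for n in tree.leaves()]
            dists = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
            diameter = max(dists[u][v] for u in leaves for v in leaves)
            assert max_depth(rooted.root) == pytest.approx(diameter / 2)


def random_tree(rng, nleaves):
    from csindel.tree import Node
    nodes = [Node(name=chr(97 + i), length=float(rng.uniform(0.1, 2)))
             for i in range(nleaves)]
    while len(nodes) > 3:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((i, j))
        parent = Node(length=float(rng.uniform(0.1, 2)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root)


class TestMonophyly:
    def _scheme(self, mapping):
        s = GroupScheme()
        s.custom_groups = {lab: set(mem) for lab, mem in mapping.items()}
        return s

    def test_clean_split(self):
        tree = Tree.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        rep = monophyly(tree, self._scheme({"a": ["a1", "a2"],
                                            "b": ["b1", "b2"]}), "custom")
        assert rep.monophyletic("a") and rep.monophyletic("b")

    def test_interleaved_labels_polyphyletic(self):
        tree = Tree.from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        rep = monophyly(tree, self._scheme({"a": ["a1", "a2"],
                                            "b": ["b1", "b2"]}), "custom")
        assert not rep.monophyletic("a") and not rep.monophyletic("b")
        assert rep.entries["a"]["offending"]

    def test_single_leaf_label_trivially_monophyletic(self):
        tree = Tree.from_newick("((a1:1,a2:1):1,(b1:1,c1:1):1);")
        rep = monophyly(tree, self._scheme({"a": ["a1", "a2"], "b": ["b1"],
                                            "c": ["c1"]}), "custom")
        assert rep.monophyletic("b") and rep.monophyletic("c")

    def test_unlabeled_leaf_errors(self):
        tree = Tree.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        with pytest.raises(TreeError):
            monophyly(tree, self._scheme({"a": ["a1", "a2"]}), "custom")


class TestPruningLikelihood:
    def test_two_leaf_limit_is_log_pi(self):
        aln = Alignment(ids=["a", "b"], rows=["A", "A"])
        tree = Tree.from_newick("(a:1e-9,b:1e-9);")
        pi = jtt.equilibrium_frequencies()
        ll = tree_log_likelihood(aln, tree)
        assert ll == pytest.approx(np.log(pi[jtt.AA_INDEX["A"]]), abs=1e-6)

    def test_three_leaf_matches_state_summation(self):
        rng = np.random.default_rng(4)
        alpha = jtt.AA_ORDER
        rows = ["".join(rng.choice(list(alpha), 20)) for _ in range(3)]
        aln = Alignment(ids=["a", "b", "c"], rows=rows)
        ta, tb, tc = 0.2, 0.5, 0.9
        tree = Tree.from_newick(f"(a:{ta},b:{tb},c:{tc});")
        ll = tree_log_likelihood(aln, tree)
        # independent oracle: direct sum over the internal state with expm
        pi = jtt.equilibrium_frequencies()
        Q = jtt.rate_matrix()
        Pa, Pb, Pc = (expm(Q * t) for t in (ta, tb, tc))
        total = 0.0
        for col in range(20):
            ia, ib, ic = (jtt.AA_INDEX[r[col]] for r in rows)
            site = sum(pi[x] * Pa[x, ia] * Pb[x, ib] * Pc[x, ic]
                       for x in range(20))
            total += np.log(site)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_nj_topology_beats_leaf_permutations(self, dgk):
        from csindel.alignment import strip_gap_columns
        core, _ = strip_gap_columns(dgk.alignment)
        sub = Alignment(ids=core.ids[:12], rows=core.rows[:12])
        tree = nj_tree(jtt_distance_matrix(sub))
        ll = tree_log_likelihood(sub, tree)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(len(sub.ids))
            shuffled = tree.copy()
            leaves = shuffled.leaves()
            names = [sub.ids[i] for i in perm]
            for leaf, name in zip(leaves, names):
                leaf.name = name
            assert tree_log_likelihood(sub, shuffled) <= ll + 1e-6

    def test_leaf_mismatch_errors(self):
        aln = Alignment(ids=["a", "b"], rows=["A", "A"])
        tree = Tree.from_newick("(a:0.1,x:0.1);")
        with pytest.raises(PhylogenyError):
            tree_log_likelihood(aln, tree)


class TestNewick:
    def test_roundtrip_topology_lengths_supports(self):
        text = "((a:0.100000,b:0.200000)95:0.300000,(c:0.400000,d:0.500000)80:0.600000);"
        tree = Tree.from_newick(text)
        assert tree.newick() == text

    def test_fixture_guide_tree_roundtrip(self, dgk):
        nwk = dgk.guide_tree.newick()
        again = Tree.from_newick(nwk)
        assert again.newick() == nwk
        assert again.leaf_names() == dgk.guide_tree.leaf_names()
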