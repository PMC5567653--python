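"""Minimal phylogenetic tree container with the operations the pipeline
needs: newick I/O (parsing via dendropy), bipartition extraction,
midpoint rooting and monophyly queries.

Branch lengths are substitutions per site.  Bootstrap supports (integer
percent) live on the child node of each internal edge and are written as
internal node labels in newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    pass


@dataclass
class Node:
    name: str | None = None
    length: float | None = None     # edge to parent
    support: int | None = None      # bootstrap % on edge to parent
    children: list = field(default_factory=list)
    parent: "Node | None" = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())


@dataclass
class Tree:
    root: Node

    def leaves(self):
        return self.root.leaves()

    def leaf_names(self) -> frozenset:
        return self.root.leaf_names()

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            c = Node(n.name, n.length, n.support)
            for ch in n.children:
                c.add(clone(ch))
            return c
        return Tree(clone(self.root))

    # -- newick ----------------------------------------------------------
    def newick(self, decimals: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                base = node.name or ""
            else:
                base = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.support is not None:
                    base += str(int(node.support))
            if node.length is not None and node.parent is not None:
                base += f":{node.length:.{decimals}f}"
            return base
        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)

        def convert(dn) -> Node:
            name = dn.taxon.label if dn.taxon is not None else None
            support = None
            if dn.label is not None:
                try:
                    support = int(round(float(dn.label)))
                except ValueError:
                    name = name or dn.label
            node = Node(name=name, length=dn.edge.length, support=support)
            for ch in dn.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))

    # -- structure queries ----------------------------------------------
    def bipartitions(self) -> dict:
        """Non-trivial splits of the (unrooted) tree.

        Returns {canonical frozenset of leaf names: node} where the node
        is the child end of the defining edge.  The canonical side is
        the one *not* containing the lexicographically smallest leaf, so
        keys are rooting-invariant.
        """
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out: dict[frozenset, Node] = {}
        for node in self.root.walk():
            if node.parent is None or node.is_leaf:
                continue
            side = node.leaf_names()
            if len(side) < 2 or len(all_leaves) - len(side) < 2:
                continue
            key = frozenset(all_leaves - side) if anchor in side else side
            out.setdefault(key, node)
        return out

    def edges(self):
        """(parent, child) pairs over the whole tree."""
        for node in self.root.walk():
            for ch in node.children:
                yield node, ch

    def _adjacency(self) -> dict:
        adj: dict[int, list] = {}
        nodes = {}
        for p, c in self.edges():
            nodes[id(p)] = p
            nodes[id(c)] = c
            w = c.length or 0.0
            adj.setdefault(id(p), []).append((id(c), w))
            adj.setdefault(id(c), []).append((id(p), w))
        return adj, nodes

    def leaf_path_lengths(self) -> dict:
        """{(name_a, name_b): path length} for all leaf pairs."""
        adj, nodes = self._adjacency()
        leaves = {id(n): n.name for n in self.leaves()}
        dists = {}
        for src in leaves:
            seen = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, []):
                    if v not in seen:
                        seen[v] = seen[u] + w
                        stack.append(v)
            for dst, dname in leaves.items():
                a, b = sorted((leaves[src], dname))
                if a != b:
                    dists[(a, b)] = seen[dst]
        return dists


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths break on the lexicographically
    smallest (sorted) leaf-name pair.  All-zero branch lengths raise.
    """
    t = tree.copy()
    dists = t.leaf_path_lengths()
    if not dists or max(dists.values()) <= 0:
        raise TreeError("cannot midpoint-root: all path lengths are zero")
    dmax = max(dists.values())
    pair = min(p for p, d in dists.items() if d == dmax)
    half = dmax / 2.0

    # walk from pair[0] toward pair[1]; find the edge holding the midpoint
    name_to_leaf = {n.name: n for n in t.leaves()}
    adj, nodes = t._adjacency()
    src, dst = id(name_to_leaf[pair[0]]), id(name_to_leaf[pair[1]])
    prev = {src: None}
    stack = [src]
    while stack:
        u = stack.pop()
        for v, _ in adj[u]:
            if v not in prev:
                prev[v] = u
                stack.append(v)
    path = [dst]
    while path[-1] != src:
        path.append(prev[path[-1]])
    path.reverse()                    # node ids from src leaf to dst leaf

    acc = 0.0
    for u, v in zip(path, path[1:]):
        w = dict(adj[u])[v]
        if acc + w >= half - 1e-12:
            offset = half - acc       # distance from u along edge (u, v)
            return _reroot_on_edge(t, nodes[u], nodes[v], offset)
        acc += w
    raise TreeError("midpoint walk failed")      # pragma: no cover


def _reroot_on_edge(t: Tree, a: Node, b: Node, dist_from_a: float) -> Tree:
    """Place the root on the edge between adjacent nodes a and b,
    ``dist_from_a`` away from a.  The tree is rebuilt by reorienting the
    undirected edge set away from the new root; each edge keeps its
    length and support, assigned to its child end in the new direction.
    """
    # undirected edge attributes keyed by node-id pairs
    attrs = {}
    neighbours: dict[int, list] = {}
    nodes = {}
    for p, c in t.edges():
        nodes[id(p)], nodes[id(c)] = p, c
        attrs[frozenset((id(p), id(c)))] = (c.length, c.support)
        neighbours.setdefault(id(p), []).append(id(c))
        neighbours.setdefault(id(c), []).append(id(p))
    if id(b) not in neighbours.get(id(a), []):   # pragma: no cover
        raise TreeError("nodes not adjacent")

    def reorient(x: int, away: int) -> Node:
        old = nodes[x]
        node = Node(name=old.name)
        for y in neighbours.get(x, []):
            if y == away:
                continue
            length, support = attrs[frozenset((x, y))]
            child = reorient(y, x)
            child.length = length
            child.support = support
            node.add(child)
        return node

    length, support = attrs[frozenset((id(a), id(b)))]
    length = length or 0.0
    root = Node()
    side_a = reorient(id(a), id(b))
    side_a.length = max(dist_from_a, 0.0)
    side_a.support = support
    side_b = reorient(id(b), id(a))
    side_b.length = max(length - dist_from_a, 0.0)
    side_b.support = support
    root.add(side_a)
    root.add(side_b)
    return Tree(root)


def mrca(tree: Tree, names) -> Node:
    names = set(names)
    best = None
    for node in tree.root.walk():
        ln = node.leaf_names()
        if names <= ln and (best is None or len(ln) < len(best.leaf_names())):
            best = node
    if best is None:
        raise TreeError(f"names {sorted(names)} not all present")
    return best


def max_depth(node: Node) -> float:
    if node.is_leaf:
        return 0.0
    return max((c.length or 0.0) + max_depth(c) for c in node.children)
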