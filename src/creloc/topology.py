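"""Unrooted leaf-labelled trees, canonical topology identifiers, topology
enumeration and neighbor-joining.

Trees are stored as a plain adjacency map.  Only the *topology* of window
trees enters the weighting analysis downstream, so branch lengths are kept
but never required to be meaningful.

Canonical identifiers follow a sorted-newick normal form: the tree is
(re)rooted at the lexicographically smallest leaf and children are sorted
recursively by the smallest label they contain, so two trees share an id
iff they share an unrooted topology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


class ZeroComparableSitesError(ValueError):
    """A sample pair shares no genotyped site; its distance is undefined."""


class Tree:
    """Unrooted leaf-labelled tree as an adjacency map.

    Parameters
    ----------
    adjacency:
        ``{node: {neighbour: branch_length}}``; symmetric.
    labels:
        ``{leaf_node: label}`` for every degree-1 node.
    """

    def __init__(self, adjacency: dict[int, dict[int, float]], labels: dict[int, str]):
        self.adjacency = adjacency
        self.labels = dict(labels)
        self._validate()

    def _validate(self) -> None:
        for node, nbrs in self.adjacency.items():
            for nbr in nbrs:
                if node not in self.adjacency.get(nbr, {}):
                    raise ValueError("adjacency is not symmetric")
        leaves = {n for n, nbrs in self.adjacency.items() if len(nbrs) == 1}
        if len(self.adjacency) > 1 and set(self.labels) != leaves:
            raise ValueError("labels must cover exactly the degree-1 nodes")
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("leaf labels must be unique")

    # -- basic accessors ---------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.labels.values())

    def leaf_node(self, label: str) -> int:
        for node, lab in self.labels.items():
            if lab == label:
                return node
        raise KeyError(label)

    # -- distances ---------------------------------------------------------

    def leaf_distances(
        self, order: list[str] | None = None, unit_lengths: bool = False
    ) -> tuple[np.ndarray, list[str]]:
        """All-pairs leaf distances by BFS/DFS from each leaf.

        With ``unit_lengths`` every edge counts 1, giving the topological
        distance used for quartet-split extraction.
        """
        if order is None:
            order = self.leaf_labels
        node_of = {lab: self.leaf_node(lab) for lab in order}
        n = len(order)
        D = np.zeros((n, n))
        for i, lab in enumerate(order):
            dist = {node_of[lab]: 0.0}
            stack = [node_of[lab]]
            while stack:
                cur = stack.pop()
                for nbr, ln in self.adjacency[cur].items():
                    if nbr not in dist:
                        dist[nbr] = dist[cur] + (1.0 if unit_lengths else ln)
                        stack.append(nbr)
            for j, lab2 in enumerate(order):
                D[i, j] = dist[node_of[lab2]]
        return D, order

    # -- newick ------------------------------------------------------------

    def canonical_id(self) -> str:
        """Sorted-newick normal form (branch lengths dropped)."""
        if len(self.labels) == 1:
            return next(iter(self.labels.values()))
        root_label = min(self.labels.values())
        root = self.leaf_node(root_label)
        (anchor,) = self.adjacency[root].keys()

        def canon(node: int, parent: int) -> tuple[str, str]:
            if node in self.labels:
                lab = self.labels[node]
                return lab, lab
            subs = sorted(
                canon(nbr, node)
                for nbr in self.adjacency[node]
                if nbr != parent
            )
            return subs[0][0], "(" + ",".join(s for _, s in subs) + ")"

        return f"({root_label},{canon(anchor, root)[1]})"

    def newick(self) -> str:
        """Newick string with branch lengths, rooted at the smallest leaf."""
        if len(self.labels) == 1:
            return next(iter(self.labels.values())) + ";"
        root_label = min(self.labels.values())
        root = self.leaf_node(root_label)
        ((anchor, ln),) = self.adjacency[root].items()

        def fmt(node: int, parent: int) -> str:
            if node in self.labels:
                return self.labels[node]
            parts = []
            for nbr, length in sorted(self.adjacency[node].items()):
                if nbr != parent:
                    parts.append(f"{fmt(nbr, node)}:{length:g}")
            return "(" + ",".join(parts) + ")"

        return f"({root_label}:0,{fmt(anchor, root)}:{ln:g});"

    # -- restriction -------------------------------------------------------

    def induced_topology_id(self, picks: dict[str, str]) -> str:
        """Canonical id of the subtree induced by ``picks``.

        ``picks`` maps leaf label -> display label (e.g. sample -> group).
        Topological leaf distances restricted to the picks are additive on
        the induced subtree with strictly positive internal edges, so
        neighbor-joining on the submatrix reconstructs it exactly.
        """
        labels = sorted(picks)
        if len(labels) < 3:
            return Tree(
                {0: {1: 1.0}, 1: {0: 1.0}},
                {i: picks[lab] for i, lab in enumerate(labels)},
            ).canonical_id()
        D, _ = self.leaf_distances(order=labels, unit_lengths=True)
        sub = nj(D, [picks[lab] for lab in labels])
        return sub.canonical_id()


def tree_from_newick(text: str) -> Tree:
    """Parse a newick string (branch lengths optional) into an unrooted Tree.

    A degree-2 root produced by rooted notation is suppressed.
    """
    text = text.strip().rstrip(";")
    adjacency: dict[int, dict[int, float]] = {}
    labels: dict[int, str] = {}
    counter = itertools.count()

    def add_edge(a: int, b: int, ln: float) -> None:
        adjacency.setdefault(a, {})[b] = ln
        adjacency.setdefault(b, {})[a] = ln

    pos = 0

    def parse() -> tuple[int, float]:
        nonlocal pos
        if text[pos] == "(":
            node = next(counter)
            adjacency.setdefault(node, {})
            pos += 1
            while True:
                child, ln = parse()
                add_edge(node, child, ln)
                if text[pos] == ",":
                    pos += 1
                elif text[pos] == ")":
                    pos += 1
                    break
        else:
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            node = next(counter)
            adjacency.setdefault(node, {})
            labels[node] = text[start:pos]
        length = 1.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            length = float(text[start:pos])
        return node, length

    root, _ = parse()
    # suppress a degree-2 root left by rooted notation
    if len(adjacency[root]) == 2 and root not in labels:
        (a, la), (b, lb) = adjacency[root].items()
        del adjacency[a][root]
        del adjacency[b][root]
        del adjacency[root]
        add_edge(a, b, la + lb)
    return Tree(adjacency, labels)


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


@dataclass(frozen=True)
class TopologySet:
    """All unrooted leaf-labelled binary topologies on a set of group labels,
    canonically identified; for G labels there are (2G-5)!! of them."""

    group_labels: tuple[str, ...]
    topology_ids: tuple[str, ...]
    _index: dict[str, int] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self._index.update({t: i for i, t in enumerate(self.topology_ids)})

    def __len__(self) -> int:
        return len(self.topology_ids)

    def index(self, topology_id: str) -> int:
        return self._index[topology_id]


def enumerate_topologies(group_labels: list[str]) -> TopologySet:
    """Enumerate all unrooted binary leaf-labelled topologies on the labels
    by recursive edge insertion (|result| = (2G-5)!!)."""
    labels = sorted(set(group_labels))
    if len(labels) != len(group_labels):
        raise ValueError("group labels must be unique")
    if len(labels) < 3:
        raise ValueError("need at least 3 group labels")

    # seed: the unique topology on the first three labels
    seed_adj = {0: {3: 1.0}, 1: {3: 1.0}, 2: {3: 1.0}, 3: {0: 1.0, 1: 1.0, 2: 1.0}}
    seed_labels = {i: labels[i] for i in range(3)}
    trees = [(seed_adj, seed_labels, 4)]

    for k in range(3, len(labels)):
        new_trees = []
        for adj, labs, next_node in trees:
            edges = {
                tuple(sorted((a, b))) for a, nbrs in adj.items() for b in nbrs
            }
            for a, b in sorted(edges):
                adj2 = {n: dict(nbrs) for n, nbrs in adj.items()}
                mid, leaf = next_node, next_node + 1
                del adj2[a][b]
                del adj2[b][a]
                for u, v in ((a, mid), (b, mid), (leaf, mid)):
                    adj2.setdefault(u, {})[v] = 1.0
                    adj2.setdefault(v, {})[u] = 1.0
                labs2 = dict(labs)
                labs2[leaf] = labels[k]
                new_trees.append((adj2, labs2, next_node + 2))
        trees = new_trees

    ids = sorted(Tree(adj, labs).canonical_id() for adj, labs, _ in trees)
    if len(set(ids)) != len(ids):  # pragma: no cover - internal consistency
        raise AssertionError("duplicate canonical ids in enumeration")
    return TopologySet(tuple(labels), tuple(ids))


def quartet_topology_id(pair1: tuple[str, str], pair2: tuple[str, str]) -> str:
    """Canonical id of the 4-leaf topology with split pair1 | pair2."""
    a, b = pair1
    c, d = pair2
    adj = {
        0: {4: 1.0},
        1: {4: 1.0},
        2: {5: 1.0},
        3: {5: 1.0},
        4: {0: 1.0, 1: 1.0, 5: 1.0},
        5: {2: 1.0, 3: 1.0, 4: 1.0},
    }
    return Tree(adj, {0: a, 1: b, 2: c, 3: d}).canonical_id()


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------


def nj(D: np.ndarray, labels: list[str]) -> Tree:
    """Neighbor-joining on a distance matrix.

    Deterministic: ties in the Q criterion are broken by the lexicographically
    smallest (min, max) pair of representative leaf labels, where an internal
    node is represented by the smallest leaf label beneath it.  Negative
    branch-length estimates are clamped to zero (topology is unaffected).
    Exact on additive matrices.
    """
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = {i: labels[i] for i in range(n)}

    def add_edge(a: int, b: int, ln: float) -> None:
        ln = max(ln, 0.0)
        adjacency.setdefault(a, {})[b] = ln
        adjacency.setdefault(b, {})[a] = ln

    active = list(range(n))
    reps = {i: labels[i] for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(n) if i < j}

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    next_node = n
    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                q = (r - 2) * d(a, b) - rowsum[a] - rowsum[b]
                tie = tuple(sorted((reps[a], reps[b])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        u = next_node
        next_node += 1
        la = 0.5 * d(a, b) + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        lb = d(a, b) - la
        add_edge(a, u, la)
        add_edge(b, u, lb)
        for c in active:
            if c not in (a, b):
                dist[(min(c, u), max(c, u))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = [c for c in active if c not in (a, b)] + [u]
        reps[u] = min(reps[a], reps[b])

    if len(active) == 3:
        a, b, c = active
        u = next_node
        add_edge(a, u, 0.5 * (d(a, b) + d(a, c) - d(b, c)))
        add_edge(b, u, 0.5 * (d(a, b) + d(b, c) - d(a, c)))
        add_edge(c, u, 0.5 * (d(a, c) + d(b, c) - d(a, b)))
    else:
        a, b = active
        add_edge(a, b, d(a, b))

    return Tree(adjacency, leaf_labels)


def tree_splits(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions (represented by the side not containing the
    smallest label) of an unrooted tree; the standard topology fingerprint."""
    all_labels = set(tree.labels.values())
    smallest = min(all_labels)
    splits: set[frozenset[str]] = set()
    for a, nbrs in tree.adjacency.items():
        for b in nbrs:
            if a > b:
                continue
            # leaves on the b-side of edge (a, b)
            seen = {a, b}
            stack = [b]
            side = set()
            while stack:
                cur = stack.pop()
                if cur in tree.labels:
                    side.add(tree.labels[cur])
                for nbr in tree.adjacency[cur]:
                    if nbr not in seen:
                        seen.add(nbr)
                        stack.append(nbr)
            if smallest in side:
                side = all_labels - side
            if 2 <= len(side) <= len(all_labels) - 2:
                splits.add(frozenset(side))
    return splits
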