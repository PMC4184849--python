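"""Equal-weights parsimony: Fitch scoring, random-addition starting trees,
TBR branch swapping, and scoring of the equally-optimal solution set.

Binary characters are scored with the Fitch dynamic program; a missing
cell carries the full state set {0, 1}, so it never forces a change.
The search mirrors the classic heuristic: stepwise random-addition
starting trees, then hill-climbing through the tree-bisection-and-
reconnection (TBR) neighborhood (bisect every internal branch, reconnect
every pair of branches in the two fragments) until no neighbor improves,
pooling all distinct equally optimal topologies across replicates.

TBR neighbors are scored incrementally: for each bisection the Fitch
state set that a virtual root would carry on every branch of each
fragment is computed with one up-pass and one down-pass, after which any
reconnection costs only a per-character disjointness test (score of the
joined tree = score(A) + score(B) + #characters whose root sets are
disjoint; the Fitch score of a fragment does not depend on where it is
rooted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import MISSING, CharacterMatrix
from .trees import Node, Tree, bipartitions, majority_rule_consensus, rf_distance

__all__ = [
    "ParsimonySearchConfig",
    "fitch_score",
    "random_addition_tree",
    "tbr_search",
    "tbr_neighbors",
    "score_solution_set",
]


@dataclass
class ParsimonySearchConfig:
    """Heuristic-search settings (desk-scale defaults; classic full-scale
    analyses use on the order of 1000 random-addition replicates)."""

    n_replicates: int = 10
    seed: int | None = None
    max_trees_retained: int = 1000
    swap: str = "tbr"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.swap not in ("tbr", "none"):
            raise ValueError("swap must be 'tbr' or 'none'")


def _leaf_masks(matrix: CharacterMatrix) -> dict[str, np.ndarray]:
    masks = {}
    for label, row in zip(matrix.taxa, matrix.data):
        m = np.empty(row.size, dtype=np.uint8)
        m[row == 0] = 1
        m[row == 1] = 2
        m[row == MISSING] = 3
        masks[label] = m
    return masks


def fitch_score(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum number of state changes over all characters (Fitch).

    Missing tips carry {0, 1}; the score is independent of rooting.
    An empty matrix scores 0 with a warning.
    """
    if matrix.n_characters == 0:
        warnings.warn("empty matrix: parsimony score is 0", stacklevel=2)
        return 0
    masks = _leaf_masks(matrix)
    return _fitch_from_masks(tree, masks)


def _fitch_from_masks(tree: Tree, masks: dict[str, np.ndarray]) -> int:
    score = 0
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            sets[id(node)] = masks[node.label]
            continue
        acc = sets.pop(id(node.children[0]))
        for child in node.children[1:]:
            other = sets.pop(id(child))
            inter = acc & other
            empty = inter == 0
            score += int(empty.sum())
            acc = np.where(empty, acc | other, inter)
        sets[id(node)] = acc
    return score


# ---------------------------------------------------------------------------
# random-addition starting trees
# ---------------------------------------------------------------------------


def random_addition_tree(matrix: CharacterMatrix, seed: int | None = None) -> Tree:
    """Stepwise-addition tree: taxa in random order, each placed on the
    branch that minimizes the Fitch score, ties broken uniformly at random.

    Output is a fully resolved rooted binary tree (unit branch lengths).
    """
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    order = [matrix.taxa[i] for i in rng.permutation(matrix.n_taxa)]
    masks = _leaf_masks(matrix)

    root = Node()
    root.add_child(Node(order[0], 1.0))
    root.add_child(Node(order[1], 1.0))
    tree = Tree(root)

    for label in order[2:]:
        candidates = [n for n in tree.postorder() if n.parent is not None]
        scores = np.empty(len(candidates))
        for i, target in enumerate(candidates):
            mid, leaf = _insert_on_edge(target, label)
            scores[i] = _fitch_from_masks(tree, masks)
            _remove_insertion(mid, leaf)
        best = np.flatnonzero(scores == scores.min())
        target = candidates[int(rng.choice(best))]
        _insert_on_edge(target, label)
    return tree


def _insert_on_edge(target: Node, label: str) -> tuple[Node, Node]:
    parent = target.parent
    mid = Node(length=1.0)
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    mid.add_child(target)
    leaf = mid.add_child(Node(label, 1.0))
    return mid, leaf


def _remove_insertion(mid: Node, leaf: Node) -> None:
    parent = mid.parent
    target = next(c for c in mid.children if c is not leaf)
    parent.children[parent.children.index(mid)] = target
    target.parent = parent


# ---------------------------------------------------------------------------
# unrooted adjacency representation for TBR
# ---------------------------------------------------------------------------


class _UTree:
    """Unrooted binary tree as an adjacency map (internal degree 3)."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        i = self._next
        self._next += 1
        self.adj[i] = set()
        if label is not None:
            self.label[i] = label
        return i

    def connect(self, a: int, b: int) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)

    def disconnect(self, a: int, b: int) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)

    def edges(self) -> list[tuple[int, int]]:
        return [(a, b) for a in self.adj for b in self.adj[a] if a < b]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.edges()
                if a not in self.label and b not in self.label]

    def copy(self) -> "_UTree":
        out = _UTree()
        out.adj = {k: set(v) for k, v in self.adj.items()}
        out.label = dict(self.label)
        out._next = self._next
        return out

    @classmethod
    def from_tree(cls, tree: Tree) -> "_UTree":
        ut = cls()
        ids: dict[int, int] = {}
        for node in tree.postorder():
            ids[id(node)] = ut.new_node(node.label if node.is_leaf() else None)
            for child in node.children:
                ut.connect(ids[id(node)], ids[id(child)])
        root = ids[id(tree.root)]
        if len(ut.adj[root]) == 2:  # suppress the degree-2 root
            a, b = ut.adj[root]
            ut.disconnect(root, a)
            ut.disconnect(root, b)
            ut.connect(a, b)
            del ut.adj[root]
        return ut

    def to_tree(self) -> Tree:
        """Re-root on an arbitrary edge (unit branch lengths)."""
        a, b = self.edges()[0]
        visited = {a, b}

        def build(node: int) -> Node:
            out = Node(self.label.get(node), 1.0)
            for nbr in self.adj[node]:
                if nbr not in visited:
                    visited.add(nbr)
                    out.add_child(build(nbr))
            return out

        root = Node()
        root.add_child(build(a))
        root.add_child(build(b))
        return Tree(root)


def _fitch_combine(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    inter = s1 & s2
    return np.where(inter == 0, s1 | s2, inter)


class _Fragment:
    """One side of a bisection: suppressed adjacency rooted at a leaf,
    with per-edge virtual-root Fitch sets and the fragment score."""

    def __init__(self, ut: _UTree, nodes: set[int], cut: int,
                 masks: dict[str, np.ndarray], n_chars: int):
        # local adjacency with the cut vertex suppressed
        adj = {x: set(n for n in ut.adj[x] if n in nodes) for x in nodes}
        nbrs = list(adj[cut])
        if len(nbrs) == 2:
            a, b = nbrs
            adj[a].discard(cut)
            adj[b].discard(cut)
            adj[a].add(b)
            adj[b].add(a)
            del adj[cut]
            self.suppressed: tuple | None = (cut, a, b)
        else:  # cut vertex kept (should not happen for internal bisection)
            self.suppressed = None
        self.adj = adj
        self.leaf_edge = len(adj) == 2  # two leaves joined by one edge

        root = next(x for x in adj if x in ut.label)
        label = ut.label
        up: dict[int, np.ndarray] = {}
        parent: dict[int, int] = {}
        order: list[int] = []
        stack = [root]
        seen = {root}
        while stack:
            x = stack.pop()
            order.append(x)
            for nbr in adj[x]:
                if nbr not in seen:
                    seen.add(nbr)
                    parent[nbr] = x
                    stack.append(nbr)
        score = np.zeros(n_chars, dtype=np.int64)
        for x in reversed(order):
            if x in label:
                up[x] = masks[label[x]]
            else:
                kids = [n for n in adj[x] if n != parent.get(x)]
                acc = up[kids[0]]
                for k in kids[1:]:
                    inter = acc & up[k]
                    empty = inter == 0
                    score += empty
                    acc = np.where(empty, acc | up[k], inter)
                up[x] = acc
        # fold the leaf-root's own mask
        child = next(iter(adj[root]))
        inter = masks[label[root]] & up[child]
        empty = inter == 0
        score += empty
        self.score = int(score.sum())

        down: dict[int, np.ndarray] = {child: masks[label[root]]}
        for x in order:
            if x in label or x == root:
                continue
            kids = [n for n in adj[x] if n != parent[x]]
            for k in kids:
                ctx = down[x]
                for sib in kids:
                    if sib != k:
                        ctx = _fitch_combine(ctx, up[sib])
                down[k] = ctx
        # virtual-root set on every edge (child -> parent edge)
        self.edge_nodes: list[int] = [x for x in order if x != root]
        self.rootsets = np.stack(
            [_fitch_combine(up[x], down[x]) for x in self.edge_nodes])
        self.parent = parent


def tbr_neighbors(ut: _UTree, masks: dict[str, np.ndarray], n_chars: int,
                  rng: np.random.Generator | None = None):
    """Yield (score, rebuild_callable) for every TBR neighbor of ``ut``.

    Bisections (internal edges) and reconnection pairs are visited in a
    seeded random order when ``rng`` is given.
    """
    internal = ut.internal_edges()
    if rng is not None:
        internal = [internal[i] for i in rng.permutation(len(internal))]
    for u, v in internal:
        nodes_a = _component(ut, u, v)
        nodes_b = set(ut.adj) - nodes_a
        frag_a = _Fragment(ut, nodes_a, u, masks, n_chars)
        frag_b = _Fragment(ut, nodes_b, v, masks, n_chars)
        base = frag_a.score + frag_b.score
        # joint disjointness counts for all reconnection pairs at once
        joins = (frag_a.rootsets[:, None, :] & frag_b.rootsets[None, :, :]) == 0
        extra = joins.sum(axis=2)
        pairs = [(i, j) for i in range(len(frag_a.edge_nodes))
                 for j in range(len(frag_b.edge_nodes))]
        if rng is not None:
            pairs = [pairs[i] for i in rng.permutation(len(pairs))]
        for i, j in pairs:
            score = base + int(extra[i, j])
            yield score, _Reconnection(ut, (u, v), frag_a, i, frag_b, j)


class _Reconnection:
    """Deferred construction of one TBR neighbor."""

    def __init__(self, ut, cut_edge, frag_a, i, frag_b, j):
        self.ut, self.cut_edge = ut, cut_edge
        self.frag_a, self.i, self.frag_b, self.j = frag_a, i, frag_b, j

    def build(self) -> _UTree:
        out = self.ut.copy()
        u, v = self.cut_edge
        out.disconnect(u, v)
        for frag in (self.frag_a, self.frag_b):
            cut, a, b = frag.suppressed
            out.disconnect(cut, a)
            out.disconnect(cut, b)
            out.connect(a, b)
            del out.adj[cut]
        hubs = []
        for frag, idx in ((self.frag_a, self.i), (self.frag_b, self.j)):
            x = frag.edge_nodes[idx]
            p = frag.parent[x]
            hub = out.new_node()
            out.disconnect(p, x)
            out.connect(p, hub)
            out.connect(hub, x)
            hubs.append(hub)
        out.connect(hubs[0], hubs[1])
        return out


def _component(ut: _UTree, start: int, blocked: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for nbr in ut.adj[x]:
            if nbr != blocked and nbr not in seen:
                if x == start and nbr == blocked:
                    continue
                seen.add(nbr)
                stack.append(nbr)
    seen.discard(blocked)
    return seen


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def _splits_key(tree: Tree) -> frozenset:
    return frozenset(bipartitions(tree))


def tbr_search(
    matrix: CharacterMatrix, config: ParsimonySearchConfig | None = None
) -> tuple[list[Tree], int]:
    """Heuristic parsimony search; returns (equally optimal trees, best score).

    Each replicate starts from a random-addition tree and hill-climbs by
    first-improvement TBR (randomized neighbor order) until no neighbor is
    strictly better; the local optimum's equal-score neighbors are swept
    up as well.  Topologies achieving the pooled best score, deduplicated
    by bipartition-set identity, are returned (capped at
    ``max_trees_retained``, with a warning on truncation).
    """
    if config is None:
        config = ParsimonySearchConfig()
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if matrix.n_characters == 0 or all(
        len(np.unique(col[col != MISSING])) <= 1 for col in matrix.data.T
    ):
        warnings.warn("no variable characters: every topology is equally "
                      "parsimonious", stacklevel=2)
    masks = _leaf_masks(matrix)
    n_chars = matrix.n_characters
    rng = np.random.default_rng(config.seed)

    best_score: int | None = None
    pool: dict[frozenset, Tree] = {}
    truncated = False

    for _ in range(config.n_replicates):
        start = random_addition_tree(matrix, seed=int(rng.integers(2**31)))
        ut = _UTree.from_tree(start)
        score = fitch_score(start, matrix) if n_chars else 0
        if config.swap == "tbr" and n_chars:
            improving = True
            while improving:
                improving = False
                for nb_score, reconnection in tbr_neighbors(ut, masks, n_chars, rng):
                    if nb_score < score:
                        ut = reconnection.build()
                        score = nb_score
                        improving = True
                        break
        if best_score is None or score < best_score:
            best_score = score
            pool.clear()
            truncated = False
        if score == best_score:
            candidates = [ut.to_tree()]
            if config.swap == "tbr" and n_chars:
                for nb_score, reconnection in tbr_neighbors(ut, masks, n_chars, None):
                    if nb_score == best_score:
                        candidates.append(reconnection.build().to_tree())
            for tree in candidates:
                key = _splits_key(tree)
                if key not in pool:
                    if len(pool) >= config.max_trees_retained:
                        truncated = True
                        break
                    pool[key] = tree
    if truncated:
        warnings.warn(
            f"equally optimal set truncated at {config.max_trees_retained} trees",
            stacklevel=2,
        )
    return list(pool.values()), int(best_score)


def score_solution_set(trees: Sequence[Tree], true_tree: Tree) -> tuple[float, int]:
    """(mean RF over the solution set, RF of its majority-rule consensus).

    The averaged score treats each equally parsimonious tree as an
    alternative optimal estimate; the consensus score summarizes the set
    with one tree first.
    """
    if not trees:
        raise ValueError("empty solution set")
    mean_rf = float(np.mean([rf_distance(t, true_tree) for t in trees]))
    consensus = majority_rule_consensus(list(trees))
    return mean_rf, rf_distance(consensus, true_tree)
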