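"""Phylogenetic tree container, newick/NEXUS I/O, and topology comparison.

Trees are rooted, node-based structures with branch lengths in units of
expected character changes per character.  Topological comparisons
(bipartitions, Robinson-Foulds distance, majority-rule consensus) treat
trees as unrooted: the rooting used for simulation and likelihood work is
never scored.

A bipartition (split) is represented canonically as the frozenset of leaf
labels on the side *not* containing the lexicographically smallest label,
so equal splits always compare equal regardless of orientation.  Only
non-trivial splits (both sides with >= 2 leaves) are ever reported; a fully
resolved unrooted tree of N leaves has exactly N - 3 of them.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_nexus_trees",
    "write_nexus_trees",
    "bipartitions",
    "rf_distance",
    "max_rf",
    "rescaled_error",
    "majority_rule_consensus",
]


class NewickParseError(ValueError):
    """Raised when a newick/NEXUS tree string cannot be parsed."""


class Node:
    """A node in a rooted tree: leaves carry a label, internals do not."""

    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.label = label

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self


class Tree:
    """A rooted tree with labelled leaves and optional fossil flags.

    Parameters
    ----------
    root:
        Root node.  For model (simulation) trees the root has degree 2 and
        every other internal node has two children (binary).  Consensus
        trees may contain polytomies.
    fossil_labels:
        Leaf labels flagged as fossil taxa (missing data is concentrated in
        these rows by :func:`mkphylo.simulate.mask_fossil_cells`).
    """

    def __init__(self, root: Node, fossil_labels: Iterable[str] = ()):
        self.root = root
        self.fossil_labels = frozenset(fossil_labels)

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf():
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    @property
    def taxa(self) -> list[str]:
        """Sorted leaf labels."""
        return sorted(n.label for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf())

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)

    # -- validation ----------------------------------------------------

    def validate(self, require_binary: bool = True, require_lengths: bool = False) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            dupes = sorted(l for l, c in Counter(labels).items() if c > 1)
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if any(not l for l in labels):
            raise ValueError("empty leaf label")
        for node in self.postorder():
            if node.parent is not None and node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length}")
            if require_lengths and node.parent is not None and node.length is None:
                raise ValueError("tree is missing branch lengths")
            if require_binary and node.children:
                expected = 2
                if len(node.children) != expected:
                    raise ValueError(
                        f"non-binary node with {len(node.children)} children "
                        "(rooted binary trees require exactly 2)"
                    )

    # -- copying -------------------------------------------------------

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return Tree(_copy(self.root), self.fossil_labels)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Tree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# newick / NEXUS I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: "dendropy.Tree", fossil_labels: Iterable[str] = ()) -> Tree:
    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(label=label if not dnode.child_nodes() else None,
                    length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Tree(convert(dtree.seed_node), fossil_labels)


def parse_newick(text: str, fossil_labels: Iterable[str] = ()) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Raises :class:`NewickParseError` (naming the offending position when
    available) on malformed input.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from None
    return _from_dendropy(dtree, fossil_labels)


def _newick_parts(node: Node) -> str:
    if node.is_leaf():
        body = node.label or ""
    else:
        body = "(" + ",".join(_newick_parts(c) for c in node.children) + ")"
    if node.length is not None and node.parent is not None:
        body += f":{node.length:.10g}"
    return body


def write_newick(tree: Tree) -> str:
    """Serialize to newick (unquoted labels, decimal branch lengths)."""
    return _newick_parts(tree.root) + ";"


def read_nexus_trees(text: str) -> list[Tree]:
    """Read every tree from a NEXUS TREES block (translate table honoured)."""
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed NEXUS trees: {exc}") from None
    return [_from_dendropy(t) for t in trees]


def write_nexus_trees(trees: Sequence[Tree], names: Sequence[str] | None = None) -> str:
    """Write a NEXUS TREES block (no translate table, unrooted flag set)."""
    lines = ["#NEXUS", "BEGIN TREES;"]
    for i, tree in enumerate(trees):
        name = names[i] if names is not None else f"tree_{i + 1}"
        lines.append(f"    TREE {name} = [&U] {write_newick(tree)}")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# bipartitions and Robinson-Foulds distance
# ---------------------------------------------------------------------------


def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial splits of the unrooted form of ``tree``.

    Each split is the frozenset of labels on the side not containing the
    smallest label.  Fully resolved unrooted binary trees of N >= 4 leaves
    yield exactly N - 3 splits; trees with < 4 leaves yield the empty set.
    """
    labels = frozenset(n.label for n in tree.leaves())
    n = len(labels)
    if n < 4:
        return set()
    ref = min(labels)
    splits: set[frozenset] = set()
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf():
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is None:
            continue
        block = below[id(node)]
        if ref in block:
            block = labels - block
        if 2 <= len(block) <= n - 2:
            splits.add(block)
    return splits


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Unweighted Robinson-Foulds (symmetric) distance between two trees.

    Counts non-trivial splits present in exactly one of the two unrooted
    topologies; both the presence of incorrect splits and the absence of
    correct ones contribute, so the maximum for fully resolved N-leaf
    trees is 2(N - 3).
    """
    l1 = frozenset(n.label for n in t1.leaves())
    l2 = frozenset(n.label for n in t2.leaves())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first={sorted(l1 - l2)}, "
            f"only in second={sorted(l2 - l1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def max_rf(n_taxa: int) -> int:
    """Maximum symmetric distance between fully resolved trees: 2(N - 3)."""
    if n_taxa < 4:
        return 0
    return 2 * (n_taxa - 3)


def rescaled_error(rf: int, n_taxa: int) -> float:
    """Rescale a symmetric distance so that the maximum 2(N - 3) is 100%."""
    ceiling = max_rf(n_taxa)
    if ceiling == 0:
        raise ValueError("rescaled error undefined for fewer than 4 taxa")
    if not 0 <= rf <= ceiling:
        raise ValueError(f"rf={rf} outside [0, {ceiling}] for {n_taxa} taxa")
    return 100.0 * rf / ceiling


# ---------------------------------------------------------------------------
# majority-rule consensus
# ---------------------------------------------------------------------------


def split_frequencies(trees: Sequence[Tree]) -> dict[frozenset, float]:
    """Frequency of every observed non-trivial split among ``trees``."""
    if not trees:
        raise ValueError("empty tree sequence")
    counts: Counter = Counter()
    for tree in trees:
        counts.update(bipartitions(tree))
    k = len(trees)
    return {split: c / k for split, c in counts.items()}


def majority_rule_consensus(
    trees: Sequence[Tree],
    threshold: float = 0.5,
    return_frequencies: bool = False,
):
    """Majority-rule consensus of a tree sample.

    Contains exactly the non-trivial splits whose frequency is strictly
    greater than ``threshold`` (default 0.5, the standard majority rule;
    50% ties are excluded).  For threshold >= 0.5 the retained splits are
    pairwise compatible, so the consensus always exists; it may be
    unresolved (polytomies).
    """
    if not trees:
        raise ValueError("empty tree sequence")
    if not 0.5 <= threshold < 1.0 + 1e-12:
        raise ValueError("threshold must lie in [0.5, 1]")
    labels = frozenset(n.label for n in trees[0].leaves())
    for t in trees[1:]:
        if frozenset(n.label for n in t.leaves()) != labels:
            raise ValueError("trees must share one leaf set")
    freqs = split_frequencies(trees)
    kept = [s for s, f in freqs.items() if f > threshold]
    tree = _tree_from_splits(labels, kept)
    if return_frequencies:
        return tree, freqs
    return tree


def _tree_from_splits(labels: frozenset, splits: Sequence[frozenset]) -> Tree:
    """Build a rooted tree realizing a compatible set of canonical splits.

    Splits are oriented away from the reference (smallest) label, so a
    compatible set forms a laminar family and can be assembled greedily
    from smallest to largest block.
    """
    top: list[tuple[frozenset, Node]] = []
    for label in sorted(labels):
        top.append((frozenset([label]), Node(label)))
    for block in sorted(splits, key=len):
        members = [(ls, nd) for ls, nd in top if ls <= block]
        covered = frozenset().union(*(ls for ls, _ in members)) if members else frozenset()
        if covered != block:  # incompatible input; cannot happen for >50% splits
            raise ValueError(f"incompatible split {sorted(block)}")
        new = Node()
        for _, nd in members:
            new.add_child(nd)
        top = [(ls, nd) for ls, nd in top if not ls <= block]
        top.append((block, new))
    root = Node()
    for _, nd in top:
        root.add_child(nd)
    return Tree(root)
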