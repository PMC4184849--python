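"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (exhaustive enumeration, closed
forms) and shares no code with the algorithms under test beyond the tree
container and the scalar transition probability.
"""

import itertools

from mkphylo.mk import binary_transition_probability
from mkphylo.simulate import MISSING
from mkphylo.trees import Tree, parse_newick


def enum_site_likelihood(tree: Tree, taxa, column, rates) -> float:
    """Exhaustive sum over internal-node (and missing-tip) states,
    averaged over equi-probable rate categories."""
    nodes = list(tree.postorder())
    leaves = {n.label: n for n in nodes if not n.children}
    fixed = {}
    free = [n for n in nodes if n.children]
    for label, state in zip(taxa, column):
        if state == MISSING:
            free.append(leaves[label])
        else:
            fixed[id(leaves[label])] = int(state)
    total = 0.0
    for r in rates:
        acc = 0.0
        for states in itertools.product((0, 1), repeat=len(free)):
            smap = dict(fixed)
            smap.update({id(n): s for n, s in zip(free, states)})
            p = 0.5  # stationary root frequency
            for n in nodes:
                if n.parent is None:
                    continue
                p *= binary_transition_probability(
                    smap[id(n.parent)], smap[id(n)], n.length * r)
            acc += p
        total += acc / len(rates)
    return total


def fitch_bruteforce(tree: Tree, matrix) -> int:
    """Minimum changes over all internal-node state assignments, summed
    over characters; missing tips are free to take either state."""
    nodes = list(tree.postorder())
    leaves = {n.label: n for n in nodes if not n.children}
    total = 0
    for j in range(matrix.n_characters):
        fixed = {}
        free = [n for n in nodes if n.children]
        for label in matrix.taxa:
            state = int(matrix.row(label)[j])
            if state == MISSING:
                free.append(leaves[label])
            else:
                fixed[id(leaves[label])] = state
        best = None
        for states in itertools.product((0, 1), repeat=len(free)):
            smap = dict(fixed)
            smap.update({id(n): s for n, s in zip(free, states)})
            changes = sum(
                1 for n in nodes if n.parent is not None
                and smap[id(n)] != smap[id(n.parent)]
            )
            if best is None or changes < best:
                best = changes
        total += best
    return total


def _rooted_shapes(labels):
    """All rooted binary tree shapes over ``labels`` as nested tuples."""
    if len(labels) == 1:
        return [labels[0]]
    shapes = []
    first, rest = labels[0], labels[1:]

    def insert(shape, leaf):
        # returns shapes with `leaf` attached on every edge incl. above root
        out = [(shape, leaf)]
        if isinstance(shape, tuple):
            left, right = shape
            out += [(l, right) for l in insert(left, leaf)]
            out += [(left, r) for r in insert(right, leaf)]
        return out

    shapes = [first]
    for leaf in rest:
        shapes = [s for shape in shapes for s in insert(shape, leaf)]
    return shapes


def _to_newick(shape) -> str:
    if isinstance(shape, tuple):
        return "(" + ",".join(_to_newick(s) for s in shape) + "):1"
    return f"{shape}:1"


def all_unrooted_topologies(labels):
    """Every unrooted binary topology on ``labels`` (as rooted Trees with
    unit branch lengths); count is (2n - 5)!! for n labels."""
    anchor, rest = labels[0], list(labels[1:])
    trees = []
    for shape in _rooted_shapes(rest):
        nwk = f"({anchor}:1,{_to_newick(shape)});"
        trees.append(parse_newick(nwk))
    return trees


def double_factorial_topology_count(n: int) -> int:
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out
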