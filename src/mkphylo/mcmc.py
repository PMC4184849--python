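"""Metropolis-Hastings MCMC over topology, branch lengths, and gamma shape
under the binary Mk likelihood, summarized by majority-rule consensus.

The sampler targets the posterior proportional to

    L(data | tree, lengths, alpha) * prior(lengths) * prior(alpha)

with a uniform prior over fully resolved (unrooted) topologies and
independent exponential priors on branch lengths and on the discrete-
gamma shape.  Trees are stored rooted (the likelihood is invariant to the
root position under this reversible, stationary model); every unrooted
topology has the same number of rooted representations, so a uniform
rooted-topology target marginalizes to the uniform unrooted prior.

Moves (chosen by weight each generation):

* ``nni`` - nearest-neighbor interchange: pick a non-root internal node v
  uniformly, swap one of its children (uniform) with v's sibling, both
  subtrees keeping their stem branches.  Every tree has exactly 2(N - 2)
  such moves and each is its own inverse, so the proposal is symmetric.
* ``swap`` - subtree exchange: pick uniformly an unordered pair of
  non-root nodes that are neither nested nor siblings and exchange the
  two subtrees (stems travel with the subtrees, so the branch-length set
  is unchanged).  The number of valid pairs depends on the topology, so
  the Hastings ratio is n_pairs(current) / n_pairs(proposed).  This plays
  the wider-jump role of SPR while avoiding any branch-length resizing.
* ``blmult`` - branch-length multiplier: t' = t * exp(tuning * (u - 1/2))
  on a uniformly chosen branch; Hastings ratio t'/t.
* ``treescale`` - the same multiplier applied to every branch at once
  (Hastings ratio c^n_edges), which lets the chain traverse tree-length
  scales quickly when the data demand a much longer or shorter tree than
  the starting state.
* ``shapemult`` - same multiplier applied to the gamma shape (only active
  when the model includes rate heterogeneity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mk import MkParams, discrete_gamma_rates, pattern_log_likelihoods, _excluded_patterns
from .simulate import CharacterMatrix
from .trees import Node, Tree, majority_rule_consensus, split_frequencies

__all__ = [
    "McmcConfig",
    "McmcRecord",
    "PosteriorSample",
    "run_mcmc",
    "summarize_posterior",
    "split_frequency_agreement",
]

_MOVES = ("nni", "swap", "blmult", "treescale", "shapemult")


@dataclass
class McmcConfig:
    """Chain settings (desk-scale defaults for ~20-taxon problems)."""

    n_generations: int = 20000
    sample_every: int = 100
    burnin_fraction: float = 0.25
    branch_length_prior_mean: float = 0.1
    shape_prior_mean: float = 1.0
    move_weights: Mapping[str, float] = field(
        default_factory=lambda: {"nni": 4.0, "swap": 2.0, "blmult": 4.0,
                                 "treescale": 1.0, "shapemult": 1.0}
    )
    tuning: float = 1.4
    seed: int | None = None
    prior_only: bool = False
    start: str = "parsimony"  # or "random"

    def __post_init__(self) -> None:
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if self.branch_length_prior_mean <= 0 or self.shape_prior_mean <= 0:
            raise ValueError("prior means must be positive")
        if any(w < 0 for w in self.move_weights.values()) or \
                not any(self.move_weights.get(m, 0) > 0 for m in ("nni", "swap")):
            raise ValueError("move weights must be non-negative with at least "
                             "one positive topology move")
        if self.start not in ("parsimony", "random"):
            raise ValueError("start must be 'parsimony' or 'random'")


@dataclass
class McmcRecord:
    generation: int
    tree: Tree
    alpha: float | None
    log_likelihood: float
    log_prior: float


@dataclass
class PosteriorSample:
    records: list[McmcRecord]
    acceptance_rates: dict[str, float]
    config: McmcConfig
    params: MkParams

    def trace_tsv(self) -> str:
        lines = ["generation\tlog_likelihood\tlog_prior\talpha\ttree_length"]
        for r in self.records:
            alpha = "" if r.alpha is None else f"{r.alpha:.6g}"
            lines.append(f"{r.generation}\t{r.log_likelihood:.6f}\t"
                         f"{r.log_prior:.6f}\t{alpha}\t{r.tree.total_length():.6f}")
        return "\n".join(lines) + "\n"

    def trees_nexus(self) -> str:
        from .trees import write_nexus_trees

        return write_nexus_trees([r.tree for r in self.records],
                                 [f"gen_{r.generation}" for r in self.records])


# ---------------------------------------------------------------------------
# tree helpers
# ---------------------------------------------------------------------------


def _random_topology(taxa: Sequence[str], rng: np.random.Generator) -> Tree:
    root = Node()
    root.add_child(Node(taxa[0]))
    root.add_child(Node(taxa[1]))
    tree = Tree(root)
    for label in taxa[2:]:
        targets = [n for n in tree.postorder() if n.parent is not None]
        target = targets[int(rng.integers(len(targets)))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(Node(label))
    return tree


def _internal_nonroot(tree: Tree) -> list[Node]:
    return [n for n in tree.postorder() if n.children and n.parent is not None]


def _apply_nni(v: Node, child_idx: int) -> tuple[Node, Node]:
    """Swap children[child_idx] of v with v's sibling; returns the swapped
    pair so the same call undoes the move."""
    u = v.parent
    c = next(ch for ch in u.children if ch is not v)
    a = v.children[child_idx]
    u.children[u.children.index(c)] = a
    a.parent = u
    v.children[child_idx] = c
    c.parent = v
    return a, c


def _swap_subtrees(x: Node, y: Node) -> None:
    px, py = x.parent, y.parent
    ix, iy = px.children.index(x), py.children.index(y)
    px.children[ix], py.children[iy] = y, x
    x.parent, y.parent = py, px


def _swap_candidates(tree: Tree) -> list[tuple[Node, Node]]:
    """Unordered pairs of non-root nodes that are neither nested nor
    siblings (both exclusions are preserved by the exchange itself, so
    the reverse move is always in the candidate set)."""
    order = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(order)}
    desc: list[int] = [0] * len(order)
    for i, n in enumerate(order):
        mask = 1 << i
        for c in n.children:
            mask |= desc[index[id(c)]]
        desc[i] = mask
    nodes = [(n, i) for i, n in enumerate(order) if n.parent is not None]
    pairs = []
    for a, (x, i) in enumerate(nodes):
        for y, j in nodes[a + 1:]:
            if desc[i] & desc[j]:  # nested (one subtree contains the other)
                continue
            if x.parent is y.parent:
                continue
            pairs.append((x, y))
    return pairs


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def run_mcmc(
    matrix: CharacterMatrix | None,
    params: MkParams,
    config: McmcConfig,
    starting_tree: Tree | None = None,
) -> PosteriorSample:
    """Run one cold Metropolis-Hastings chain; deterministic under the seed.

    ``matrix`` may be None only in prior-only mode (likelihood == 1), used
    to validate the sampler against its priors.  The chain is initialized
    from ``starting_tree`` if given, else from a random-addition parsimony
    tree (config.start == "parsimony") or a uniform random topology, with
    branch lengths (and shape, if the model has rate heterogeneity) drawn
    from their priors.
    """
    rng = np.random.default_rng(config.seed)
    prior_only = config.prior_only or matrix is None

    if matrix is not None:
        taxa = sorted(matrix.taxa)
        if matrix.n_characters == 0 and not prior_only:
            raise ValueError("empty matrix outside prior-only mode")
    elif starting_tree is not None:
        taxa = starting_tree.taxa
    else:
        raise ValueError("need a matrix or a starting tree to define the taxa")
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")

    # initial state
    if starting_tree is not None:
        tree = starting_tree.copy()
        if tree.taxa != taxa:
            raise ValueError("starting tree leaves do not match the matrix")
    elif config.start == "parsimony" and not prior_only:
        from .parsimony import random_addition_tree

        tree = random_addition_tree(matrix, seed=int(rng.integers(2**31)))
    else:
        tree = _random_topology(list(rng.permutation(taxa)), rng)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.exponential(config.branch_length_prior_mean))

    gamma = params.gamma_shape is not None
    alpha = params.gamma_shape if gamma else None

    # likelihood closure over compressed site patterns + excluded dummies
    if not prior_only:
        aligned = matrix if list(matrix.taxa) == taxa else matrix.reorder(taxa)
        patterns, counts = np.unique(aligned.data, axis=1, return_counts=True)
        dummies = _excluded_patterns(len(taxa), params.ascertainment_mode)
        all_patterns = np.concatenate([patterns, dummies], axis=1)
        n_data = patterns.shape[1]
        n_chars = matrix.n_characters

        def loglik(t: Tree, a: float | None) -> float:
            rates = (discrete_gamma_rates(a, params.n_rate_categories)
                     if gamma else np.ones(1))
            lls = pattern_log_likelihoods(t, taxa, all_patterns, rates)
            total = float((lls[:n_data] * counts).sum())
            excl = float(np.exp(lls[n_data:]).sum())
            if excl >= 1.0 - 1e-12:
                return -math.inf
            return total - n_chars * math.log1p(-excl)
    else:
        def loglik(t: Tree, a: float | None) -> float:
            return 0.0

    mu_bl = config.branch_length_prior_mean
    mu_shape = config.shape_prior_mean

    def logprior(t: Tree, a: float | None) -> float:
        lp = 0.0
        for node in t.postorder():
            if node.parent is not None:
                lp += -node.length / mu_bl - math.log(mu_bl)
        if a is not None:
            lp += -a / mu_shape - math.log(mu_shape)
        return lp

    cur_ll = loglik(tree, alpha)
    cur_lp = logprior(tree, alpha)
    if not np.isfinite(cur_ll + cur_lp):
        raise ValueError(
            f"non-finite starting posterior (lnL={cur_ll}, lnPrior={cur_lp}); "
            "check for a degenerate tree or excluded-pattern probability of 1"
        )

    moves = [m for m in _MOVES if config.move_weights.get(m, 0) > 0]
    if not gamma:
        moves = [m for m in moves if m != "shapemult"]
    weights = np.array([config.move_weights[m] for m in moves], dtype=float)
    weights /= weights.sum()

    proposed = {m: 0 for m in moves}
    accepted = {m: 0 for m in moves}
    records: list[McmcRecord] = []

    def snapshot(gen: int) -> None:
        records.append(McmcRecord(gen, tree.copy(), alpha, cur_ll, cur_lp))

    snapshot(0)
    for gen in range(1, config.n_generations + 1):
        move = moves[int(rng.choice(len(moves), p=weights))]
        proposed[move] += 1
        log_hastings = 0.0
        undo = None
        new_alpha = alpha
        new_lp = cur_lp

        if move == "nni":
            internal = _internal_nonroot(tree)
            v = internal[int(rng.integers(len(internal)))]
            idx = int(rng.integers(2))
            _apply_nni(v, idx)
            undo = ("nni", v, idx)
        elif move == "swap":
            pairs = _swap_candidates(tree)
            if not pairs:
                continue
            x, y = pairs[int(rng.integers(len(pairs)))]
            n_before = len(pairs)
            _swap_subtrees(x, y)
            n_after = len(_swap_candidates(tree))
            log_hastings = math.log(n_before) - math.log(n_after)
            undo = ("swap", x, y)
        elif move == "blmult":
            candidates = [n for n in tree.postorder() if n.parent is not None]
            node = candidates[int(rng.integers(len(candidates)))]
            old = node.length
            factor = math.exp(config.tuning * (rng.random() - 0.5))
            node.length = old * factor
            log_hastings = math.log(factor)
            new_lp = cur_lp - (node.length - old) / mu_bl
            undo = ("blmult", node, old)
        elif move == "treescale":
            edges = [n for n in tree.postorder() if n.parent is not None]
            old_lengths = [n.length for n in edges]
            factor = math.exp(config.tuning * (rng.random() - 0.5))
            delta = 0.0
            for node in edges:
                delta -= node.length * (factor - 1.0) / mu_bl
                node.length *= factor
            log_hastings = len(edges) * math.log(factor)
            new_lp = cur_lp + delta
            undo = ("treescale", edges, old_lengths)
        else:  # shapemult
            factor = math.exp(config.tuning * (rng.random() - 0.5))
            new_alpha = alpha * factor
            log_hastings = math.log(factor)
            new_lp = cur_lp - (new_alpha - alpha) / mu_shape
            undo = ("shapemult",)

        new_ll = cur_ll if prior_only else loglik(tree, new_alpha)
        log_ratio = (new_ll + new_lp) - (cur_ll + cur_lp) + log_hastings
        if math.log(rng.random()) < log_ratio:
            accepted[move] += 1
            cur_ll, cur_lp, alpha = new_ll, new_lp, new_alpha
        else:
            kind = undo[0]
            if kind == "nni":
                _apply_nni(undo[1], undo[2])
            elif kind == "swap":
                _swap_subtrees(undo[1], undo[2])
            elif kind == "blmult":
                undo[1].length = undo[2]
            elif kind == "treescale":
                for node, old in zip(undo[1], undo[2]):
                    node.length = old
            # shapemult: alpha was never committed

        if gen % config.sample_every == 0:
            snapshot(gen)

    rates = {m: (accepted[m] / proposed[m] if proposed[m] else float("nan"))
             for m in moves}
    return PosteriorSample(records, rates, config, params)


def summarize_posterior(
    sample: PosteriorSample, burnin_fraction: float | None = None
) -> tuple[Tree, dict[frozenset, float]]:
    """Majority-rule consensus of the post-burn-in trees plus the frequency
    of every observed non-trivial split."""
    if burnin_fraction is None:
        burnin_fraction = sample.config.burnin_fraction
    if not 0 <= burnin_fraction < 1:
        raise ValueError("burnin_fraction must lie in [0, 1)")
    retained = sample.records[int(len(sample.records) * burnin_fraction):]
    if not retained:
        raise ValueError("no post-burn-in samples")
    trees = [r.tree for r in retained]
    return majority_rule_consensus(trees, return_frequencies=True)


def split_frequency_agreement(
    a: PosteriorSample, b: PosteriorSample, burnin_fraction: float | None = None
) -> float:
    """Max absolute split-frequency difference between two independent
    chains (the standard convergence diagnostic; < 0.05 is good)."""
    freqs = []
    for sample in (a, b):
        bf = sample.config.burnin_fraction if burnin_fraction is None else burnin_fraction
        retained = sample.records[int(len(sample.records) * bf):]
        freqs.append(split_frequencies([r.tree for r in retained]))
    fa, fb = freqs
    keys = set(fa) | set(fb)
    if not keys:
        return 0.0
    return max(abs(fa.get(k, 0.0) - fb.get(k, 0.0)) for k in keys)
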