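"""Binary Mk likelihood machinery.

The two-state Mk model is the binary special case of the symmetric
k-state Markov model for discrete characters: both states have stationary
frequency 1/2 and the instantaneous rate matrix is normalized so that a
branch of length t expects t changes.  The closed-form transition
probabilities are

    P(same state | t)      = 1/2 + 1/2 exp(-2t)
    P(different state | t) = 1/2 - 1/2 exp(-2t).

Character likelihoods come from Felsenstein's pruning algorithm with
per-node rescaling against underflow; missing cells contribute the
uninformative partial (1, 1).  Among-character rate heterogeneity uses
the discrete-gamma approximation (equi-probable categories, mean-of-
category rates, mean exactly 1).

Morphological matrices are usually collected with an acquisition bias:
invariant (and sometimes autapomorphic) columns are never scored.  The
corrected likelihoods condition on a character being observable under the
collection scheme by dividing each site likelihood by one minus the total
probability of the excluded patterns, which for binary states is computed
exactly by summing the 2 constant patterns (variable-only conditioning,
the "Mkv" correction) or the 2 constant plus 2N singleton patterns
(parsimony-informative conditioning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .simulate import MISSING, CharacterMatrix
from .trees import Tree

__all__ = [
    "ASCERTAINMENT_MODES",
    "MkParams",
    "binary_transition_probability",
    "discrete_gamma_rates",
    "site_likelihood",
    "excluded_pattern_probability",
    "matrix_log_likelihood",
    "pattern_log_likelihoods",
]

ASCERTAINMENT_MODES = ("none", "variable", "parsimony_informative")


@dataclass
class MkParams:
    """Inference-side model settings.

    ``gamma_shape`` is the shape of the discrete-gamma distribution of
    rates across characters; ``None`` means a rate-homogeneous likelihood.
    ``ascertainment_mode`` selects the acquisition-bias conditioning:
    "none" (uncorrected Mk), "variable" (Mkv), or "parsimony_informative"
    (Mk-pars).
    """

    ascertainment_mode: str = "none"
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        if self.ascertainment_mode not in ASCERTAINMENT_MODES:
            raise ValueError(f"unknown ascertainment mode {self.ascertainment_mode!r}")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("n_rate_categories must be >= 1")

    def category_rates(self, gamma_shape: float | None = None) -> np.ndarray:
        shape = self.gamma_shape if gamma_shape is None else gamma_shape
        if shape is None:
            return np.ones(1)
        return discrete_gamma_rates(shape, self.n_rate_categories)


def binary_transition_probability(i: int, j: int, t: float) -> float:
    """P(state j at the end of a branch of length t | state i at the top).

    Branch length is measured in expected changes; rows of the implied
    2x2 matrix sum to one for every t >= 0.
    """
    if i not in (0, 1) or j not in (0, 1):
        raise ValueError("states must be 0 or 1")
    if t < 0:
        raise ValueError("branch length must be non-negative")
    decay = 0.5 * np.exp(-2.0 * t)
    return float(0.5 + decay if i == j else 0.5 - decay)


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean-of-category rates for the discrete-gamma approximation.

    Categories are equi-probable; each rate is the mean of its gamma
    (shape, mean 1) slice, so the category rates average exactly 1.
    """
    if shape <= 0:
        raise ValueError("shape must be positive")
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if n_categories == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(n_categories + 1) / n_categories,
                           a=shape, scale=1.0 / shape)
    # E[X; a < X < b] for gamma(shape, mean 1) via the regularized
    # incomplete gamma of shape+1; multiply by K for the category mean.
    mass = gammainc(shape + 1.0, edges[1:] * shape) - gammainc(shape + 1.0, edges[:-1] * shape)
    return mass * n_categories


# ---------------------------------------------------------------------------
# pruning core
# ---------------------------------------------------------------------------


def _flatten(tree: Tree, taxa: Sequence[str]):
    """Postorder arrays for pruning: (order, children-lists, lengths, leaf rows)."""
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    leaf_row = {t: i for i, t in enumerate(taxa)}
    entries = []
    for n in nodes:
        if n.is_leaf():
            if n.label not in leaf_row:
                raise ValueError(f"leaf {n.label!r} not present in taxa")
            entries.append((None, leaf_row[n.label], n.length))
        else:
            entries.append(([index[id(c)] for c in n.children], None, n.length))
    return entries


def pattern_log_likelihoods(
    tree: Tree, taxa: Sequence[str], patterns: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Log-likelihood of each column of ``patterns`` under the binary Mk model.

    ``patterns`` is (n_taxa, n_patterns) with entries 0, 1, or MISSING;
    rows follow ``taxa``.  ``rates`` are the equi-probable rate-category
    multipliers (use ``[1.0]`` for a homogeneous model); the site
    likelihood is their average.  Per-node rescaling keeps the computation
    stable for large trees and extreme rates.
    """
    patterns = np.asarray(patterns)
    if patterns.size and not (((patterns == 0) | (patterns == 1)
                               | (patterns == MISSING)).all()):
        raise ValueError("states must be 0, 1, or '?'")
    rates = np.asarray(rates, dtype=float)
    ncat = rates.size
    npat = patterns.shape[1]
    entries = _flatten(tree, taxa)

    tip = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # rows: state 0, 1, missing
    tips = tip[patterns]  # (n_taxa, npat, 2); broadcast over categories
    partials: list[np.ndarray | None] = [None] * len(entries)
    logscale = np.zeros((ncat, npat))
    since_scale = 0
    for i, (children, leaf_idx, _len) in enumerate(entries):
        if children is None:
            partials[i] = tips[leaf_idx]
            continue
        acc = None
        for c in children:
            t = entries[c][2]
            if t is None:
                raise ValueError("likelihood requires branch lengths on every edge")
            decay = 0.5 * np.exp(-2.0 * t * rates)[:, None, None]
            child = partials[c]
            up = (0.5 + decay) * child + (0.5 - decay) * child[..., ::-1]
            acc = up if acc is None else acc * up
            partials[c] = None  # release
        since_scale += 1
        if since_scale >= 8 or i == len(entries) - 1:  # rescale periodically
            peak = acc.max(axis=-1)
            peak = np.where(peak > 0.0, peak, 1.0)
            logscale += np.log(peak)
            acc = acc / peak[..., None]
            since_scale = 0
        partials[i] = acc

    root = partials[-1]
    site = 0.5 * (root[..., 0] + root[..., 1])
    with np.errstate(divide="ignore"):
        percat = np.log(site) + logscale
    # average over equi-probable categories in log space
    peak = percat.max(axis=0)
    out = peak + np.log(np.mean(np.exp(percat - peak), axis=0))
    return np.where(np.isfinite(peak), out, -np.inf)


def site_likelihood(tree: Tree, column: np.ndarray, params: MkParams) -> float:
    """Likelihood of one character (Felsenstein pruning, stationary root).

    ``column`` holds one state per taxon in sorted-taxon order (0, 1, or
    MISSING/'?'); a column of all-missing cells has likelihood exactly 1.
    With gamma heterogeneity the conditional likelihood is averaged over
    the equi-probable category rates.
    """
    column = _coerce_column(column)
    taxa = tree.taxa
    if column.shape != (len(taxa),):
        raise ValueError("column length must equal the number of leaves")
    rates = params.category_rates()
    ll = pattern_log_likelihoods(tree, taxa, column[:, None], rates)[0]
    return float(np.exp(ll))


def _coerce_column(column) -> np.ndarray:
    arr = np.asarray(column)
    if arr.dtype.kind in "UO":
        mapping = {"0": 0, "1": 1, "?": MISSING}
        try:
            arr = np.array([mapping[str(v)] for v in arr], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"invalid state {exc}") from None
    return arr.astype(np.int8)


def _excluded_patterns(n_taxa: int, mode: str) -> np.ndarray:
    """Dummy patterns excluded by an acquisition scheme, one per column."""
    if mode == "none":
        return np.zeros((n_taxa, 0), dtype=np.int8)
    constants = np.stack([np.zeros(n_taxa, np.int8), np.ones(n_taxa, np.int8)], axis=1)
    if mode == "variable":
        return constants
    singles = []
    for i in range(n_taxa):
        for state in (0, 1):
            col = np.full(n_taxa, 1 - state, dtype=np.int8)
            col[i] = state
            singles.append(col)
    return np.concatenate([constants, np.stack(singles, axis=1)], axis=1)


def excluded_pattern_probability(tree: Tree, params: MkParams) -> float:
    """Total probability of the character patterns an observer never collects.

    variable mode: the 2 constant patterns.  parsimony_informative mode:
    the constants plus the 2N autapomorphic (singleton) patterns.  none:
    0.  Computed exactly by summing pruning likelihoods of the dummy
    patterns (gamma heterogeneity handled inside).
    """
    if params.ascertainment_mode == "none":
        return 0.0
    taxa = tree.taxa
    dummies = _excluded_patterns(len(taxa), params.ascertainment_mode)
    lls = pattern_log_likelihoods(tree, taxa, dummies, params.category_rates())
    return float(np.exp(lls).sum())


def matrix_log_likelihood(tree: Tree, matrix: CharacterMatrix, params: MkParams) -> float:
    """Log-likelihood of a whole matrix with optional ascertainment correction.

    Sums per-site log-likelihoods (site patterns compressed first) and
    subtracts M * log(1 - P_excluded), the exact conditioning on every
    collected character being observable under the acquisition scheme.
    """
    from .simulate import CharacterClass, classify_matrix  # cycle-free local import

    taxa = tree.taxa
    if set(matrix.taxa) != set(taxa):
        raise ValueError("matrix taxa must match tree leaves")
    aligned = matrix if list(matrix.taxa) == taxa else matrix.reorder(taxa)

    if params.ascertainment_mode != "none" and matrix.n_characters:
        classes = classify_matrix(aligned)
        if params.ascertainment_mode == "variable":
            bad = sum(c is CharacterClass.INVARIANT for c in classes)
            if bad:
                warnings.warn(f"{bad} invariant column(s) under variable-only "
                              "conditioning (model misspecification)", stacklevel=2)
        else:
            bad = sum(c is not CharacterClass.PARSIMONY_INFORMATIVE for c in classes)
            if bad:
                warnings.warn(f"{bad} non-informative column(s) under "
                              "parsimony-informative conditioning "
                              "(model misspecification)", stacklevel=2)

    rates = params.category_rates()
    patterns, counts = np.unique(aligned.data, axis=1, return_counts=True)
    lls = pattern_log_likelihoods(tree, taxa, patterns, rates) if patterns.size else np.zeros(0)
    total = float((lls * counts).sum())

    excl = excluded_pattern_probability(tree, params)
    if excl >= 1.0 - 1e-12:
        raise ValueError("excluded-pattern probability is 1 (degenerate tree): "
                         "corrected likelihood undefined")
    return total - matrix.n_characters * float(np.log1p(-excl))
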