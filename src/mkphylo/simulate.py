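"""Model-tree generation, binary Mk character simulation, character
filtration (ascertainment schemes), and structured missing data.

The simulation emulates discrete morphological data sets of the kind seen
in paleontological studies: a tree with many short internal branches, a
designated subset of fossil leaves, binary characters evolved under a
symmetric two-state continuous-time Markov process, observer-style
filtering of invariant/uninformative columns, and missing data
concentrated either in particular rate classes of characters or in the
fossil rows.

Rate parameterization: a character's rate ``r`` is the expected number of
changes for that character summed over the whole tree, so a data set
simulated at ``mean_rate=1`` averages one expected change per character.
Internally the effective length of a branch for a character of rate ``r``
is ``branch_length * r / total_tree_length``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from io import StringIO
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import Node, Tree

__all__ = [
    "MISSING",
    "CharacterClass",
    "CharacterMatrix",
    "SimulationConfig",
    "generate_model_tree",
    "simulate_characters",
    "classify_character",
    "classify_matrix",
    "filter_matrix",
    "assign_rate_classes",
    "delete_rate_class",
    "mask_fossil_cells",
]

#: Integer code for a missing ('?') cell in the matrix array.
MISSING = -1

RATE_CLASSES = ("slow", "intermediate", "fast")
FILTRATION_SCHEMES = ("unfiltered", "variable_only", "parsimony_informative_only")


class CharacterClass(str, Enum):
    """Parsimony-oriented classification of a binary column."""

    INVARIANT = "invariant"
    VARIABLE_UNINFORMATIVE = "variable_uninformative"
    PARSIMONY_INFORMATIVE = "parsimony_informative"


@dataclass
class CharacterMatrix:
    """Taxa x binary characters, with per-character true simulating rates.

    ``data`` is an int8 array of shape (n_taxa, n_characters) holding 0, 1,
    or :data:`MISSING`.  ``true_rates`` stays aligned with the columns
    through every filtering/deletion operation.  Rows are identified by
    taxon label, never by position.
    """

    taxa: list[str]
    data: np.ndarray
    true_rates: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        self.true_rates = np.asarray(self.true_rates, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, n_characters)")
        if self.true_rates.shape != (self.data.shape[1],):
            raise ValueError("true_rates must align with columns")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.data[self.taxa.index(label)]

    def column(self, j: int) -> np.ndarray:
        return self.data[:, j]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(list(self.taxa), self.data.copy(), self.true_rates.copy())

    def subset_columns(self, idx: np.ndarray) -> "CharacterMatrix":
        idx = np.asarray(idx)
        return CharacterMatrix(list(self.taxa), self.data[:, idx], self.true_rates[idx])

    def reorder(self, taxa: Sequence[str]) -> "CharacterMatrix":
        """Return a copy with rows in the given taxon order."""
        if set(taxa) != set(self.taxa):
            raise ValueError("taxon sets differ")
        perm = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(list(taxa), self.data[perm], self.true_rates.copy())

    # -- I/O -----------------------------------------------------------

    def to_nexus(self) -> str:
        """NEXUS DATA block (datatype=standard), MrBayes-compatible."""
        sym = {0: "0", 1: "1", MISSING: "?"}
        width = max(len(t) for t in self.taxa) + 2
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_characters};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=- INTERLEAVE=NO;',
            "    MATRIX",
        ]
        for label, row in zip(self.taxa, self.data):
            seq = "".join(sym[int(v)] for v in row)
            lines.append(f"        {label:<{width}}{seq}")
        lines += ["    ;", "END;"]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_nexus(cls, text: str, true_rates: np.ndarray | None = None) -> "CharacterMatrix":
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus",
                                                  preserve_underscores=True)
        taxa = [t.label for t in dm.taxon_namespace]
        rows = []
        for taxon in dm.taxon_namespace:
            row = []
            for cell in dm[taxon]:
                s = str(cell)
                row.append(MISSING if s in "?-" else int(s))
            rows.append(row)
        data = np.array(rows, dtype=np.int8)
        if true_rates is None:
            true_rates = np.full(data.shape[1], np.nan)
        return cls(taxa, data, np.asarray(true_rates, dtype=float))

    def to_tsv(self) -> str:
        cols = [f"char_{j + 1}" for j in range(self.n_characters)]
        sym = {0: "0", 1: "1", MISSING: "?"}
        df = pd.DataFrame(
            [[sym[int(v)] for v in row] for row in self.data],
            index=self.taxa, columns=cols,
        )
        df.index.name = "taxon"
        return df.to_csv(sep="\t")

    def rates_tsv(self) -> str:
        """Sidecar table of per-character true rates and classes."""
        df = pd.DataFrame({
            "character": [f"char_{j + 1}" for j in range(self.n_characters)],
            "true_rate": self.true_rates,
            "class": [classify_character(self.data[:, j]).value
                      for j in range(self.n_characters)],
        })
        return df.to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str, rates_text: str | None = None) -> "CharacterMatrix":
        df = pd.read_csv(StringIO(text), sep="\t", index_col="taxon", dtype=str)
        data = df.replace("?", str(MISSING)).astype(np.int8).to_numpy()
        if rates_text is not None:
            rates = pd.read_csv(StringIO(rates_text), sep="\t")["true_rate"].to_numpy()
        else:
            rates = np.full(data.shape[1], np.nan)
        return cls([str(t) for t in df.index], data, rates)


@dataclass
class SimulationConfig:
    """Settings for one simulated data set.

    rate_mode "single" applies one rate to every character; "per_character"
    draws each character's rate independently from a gamma with mean
    ``mean_rate`` and shape ``gamma_shape``.  In single mode the shared
    rate is itself one gamma draw when ``gamma_shape`` is set, or exactly
    ``mean_rate`` when ``gamma_shape`` is None (useful when the rate is an
    experimental axis that must be hit exactly).
    """

    n_characters: int = 350
    rate_mode: str = "single"
    gamma_shape: float | None = 1.0
    mean_rate: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_characters < 0:
            raise ValueError("n_characters must be >= 0")
        if self.rate_mode not in ("single", "per_character"):
            raise ValueError(f"unknown rate_mode {self.rate_mode!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.rate_mode == "per_character" and self.gamma_shape is None:
            raise ValueError("per_character mode requires a gamma_shape")


# ---------------------------------------------------------------------------
# model tree generation
# ---------------------------------------------------------------------------


def generate_model_tree(
    n_taxa: int = 75,
    fossil_fraction: float = 0.2,
    total_length: float = 1.0,
    short_branch_bias: float = 2.0,
    seed: int | None = None,
    fossil_scheme: str = "shortest",
) -> Tree:
    """Generate a rooted binary model tree with many short branches.

    Branch lengths are drawn as Uniform(0,1)**short_branch_bias and then
    rescaled to sum to ``total_length``; bias > 1 concentrates mass near
    zero, mimicking empirical trees with many short internal branches as
    found in clades with fossil taxa.  ``ceil(fossil_fraction * n_taxa)``
    leaves are flagged fossil: those subtending the shortest terminal
    branches (scheme "shortest", the default) or a uniform random subset
    (scheme "random").
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    if not 0 <= fossil_fraction < 1:
        raise ValueError("fossil_fraction must lie in [0, 1)")
    if total_length <= 0 or short_branch_bias <= 0:
        raise ValueError("total_length and short_branch_bias must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    labels = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]

    root = Node()
    first, second = Node(labels[0]), Node(labels[1])
    root.add_child(first)
    root.add_child(second)
    attachable = [first, second]
    for label in labels[2:]:
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        leaf = mid.add_child(Node(label))
        attachable.extend([mid, leaf])

    tree = Tree(root)
    edges = [n for n in tree.postorder() if n.parent is not None]
    raw = rng.random(len(edges)) ** short_branch_bias
    raw *= total_length / raw.sum()
    for node, length in zip(edges, raw):
        node.length = float(length)

    n_fossil = int(np.ceil(fossil_fraction * n_taxa))
    if n_fossil:
        leaves = tree.leaves()
        if fossil_scheme == "shortest":
            ranked = sorted(leaves, key=lambda n: (n.length, n.label))
        elif fossil_scheme == "random":
            ranked = list(rng.permutation(np.array(leaves, dtype=object)))
        else:
            raise ValueError(f"unknown fossil_scheme {fossil_scheme!r}")
        tree.fossil_labels = frozenset(n.label for n in ranked[:n_fossil])
    tree.validate(require_binary=True, require_lengths=True)
    return tree


# ---------------------------------------------------------------------------
# character simulation
# ---------------------------------------------------------------------------


def simulate_characters(tree: Tree, config: SimulationConfig) -> CharacterMatrix:
    """Evolve binary characters down ``tree`` under the symmetric 2-state
    Markov process (the binary special case of the Mk model).

    Root states are drawn from the stationary frequencies (1/2, 1/2) and
    flipped along each branch with probability (1 - exp(-2 t_eff)) / 2,
    where t_eff = branch_length * rate / total_tree_length, so a character
    of rate r expects r changes over the whole tree.  Deterministic under
    ``config.seed``.
    """
    tree.validate(require_binary=True, require_lengths=True)
    rng = np.random.default_rng(config.seed)
    m = config.n_characters

    if config.rate_mode == "single":
        if config.gamma_shape is None:
            rate = config.mean_rate
        else:
            rate = float(rng.gamma(config.gamma_shape,
                                   config.mean_rate / config.gamma_shape))
            rate = max(rate, np.finfo(float).tiny)
        rates = np.full(m, rate)
    else:
        rates = rng.gamma(config.gamma_shape,
                          config.mean_rate / config.gamma_shape, size=m)
        rates = np.maximum(rates, np.finfo(float).tiny)
    if np.any(rates <= 0):
        raise ValueError("character rates must be positive")

    total = tree.total_length()
    if total <= 0:
        raise ValueError("tree must have positive total length")

    states: dict[int, np.ndarray] = {id(tree.root): rng.integers(0, 2, size=m, dtype=np.int8)}
    leaf_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is not None:
            t_eff = node.length * rates / total
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * t_eff))
            flips = rng.random(m) < p_flip
            states[id(node)] = np.where(flips, 1 - states[id(node.parent)],
                                        states[id(node.parent)]).astype(np.int8)
        if node.is_leaf():
            leaf_rows[node.label] = states[id(node)]

    taxa = sorted(leaf_rows)
    data = np.vstack([leaf_rows[t] for t in taxa]) if taxa else np.zeros((0, m), np.int8)
    return CharacterMatrix(taxa, data, rates)


# ---------------------------------------------------------------------------
# classification and filtration (ascertainment schemes)
# ---------------------------------------------------------------------------


def classify_character(column: np.ndarray) -> CharacterClass:
    """Classify one binary column (missing cells ignored).

    Invariant: at most one distinct state observed (an all-missing column
    is a degenerate invariant).  Parsimony-informative: both states occur
    at least twice.  Otherwise variable but uninformative (autapomorphy).
    """
    column = np.asarray(column)
    observed = column[column != MISSING]
    if observed.size and not np.isin(observed, (0, 1)).all():
        raise ValueError("states must be 0, 1, or missing")
    zeros = int((observed == 0).sum())
    ones = int((observed == 1).sum())
    if zeros == 0 or ones == 0:
        return CharacterClass.INVARIANT
    if zeros >= 2 and ones >= 2:
        return CharacterClass.PARSIMONY_INFORMATIVE
    return CharacterClass.VARIABLE_UNINFORMATIVE


def classify_matrix(matrix: CharacterMatrix) -> list[CharacterClass]:
    return [classify_character(matrix.data[:, j]) for j in range(matrix.n_characters)]


_SCHEME_KEEPS = {
    "unfiltered": frozenset(CharacterClass),
    "variable_only": frozenset({CharacterClass.VARIABLE_UNINFORMATIVE,
                                CharacterClass.PARSIMONY_INFORMATIVE}),
    "parsimony_informative_only": frozenset({CharacterClass.PARSIMONY_INFORMATIVE}),
}


def filter_matrix(matrix: CharacterMatrix, scheme: str) -> CharacterMatrix:
    """Drop columns excluded by an observer-style acquisition scheme.

    "unfiltered" keeps everything; "variable_only" drops invariant columns;
    "parsimony_informative_only" additionally drops autapomorphies.  Column
    order and the true-rate alignment are preserved.
    """
    if scheme not in _SCHEME_KEEPS:
        raise ValueError(f"unknown filtration scheme {scheme!r}")
    keep_classes = _SCHEME_KEEPS[scheme]
    keep = np.array([cls in keep_classes for cls in classify_matrix(matrix)], dtype=bool)
    out = matrix.subset_columns(np.flatnonzero(keep))
    if out.n_characters == 0 and matrix.n_characters > 0:
        warnings.warn(f"filtration scheme {scheme!r} removed every column", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# structured missing data
# ---------------------------------------------------------------------------


def _tertile_sizes(n: int) -> tuple[int, int, int]:
    base, rem = divmod(n, 3)
    return tuple(base + (1 if i < rem else 0) for i in range(3))  # type: ignore[return-value]


def assign_rate_classes(matrix: CharacterMatrix) -> np.ndarray:
    """Assign each character to a slow/intermediate/fast rate tertile.

    Characters are sorted ascending by their true simulating rate (ties
    broken by original column index) and cut into three contiguous groups
    of near-equal size; when the count is not divisible by 3 the earlier
    (slower) classes take the extra column.
    """
    rates = matrix.true_rates
    if matrix.n_characters == 0 or np.unique(rates).size <= 1:
        raise ValueError("rate classes require per-character rate heterogeneity")
    order = np.lexsort((np.arange(rates.size), rates))
    sizes = _tertile_sizes(rates.size)
    classes = np.empty(rates.size, dtype=object)
    start = 0
    for name, size in zip(RATE_CLASSES, sizes):
        classes[order[start:start + size]] = name
        start += size
    return classes


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def delete_rate_class(
    matrix: CharacterMatrix, rate_class: str, fraction: float, seed: int | None = None
) -> CharacterMatrix:
    """Delete a random fraction of the columns in one rate tertile.

    ``round_half_up(fraction * class_size)`` columns of the named class are
    removed uniformly at random; other classes are untouched.
    """
    if rate_class not in RATE_CLASSES:
        raise ValueError(f"unknown rate class {rate_class!r}")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    classes = assign_rate_classes(matrix)
    members = np.flatnonzero(classes == rate_class)
    k = _round_half_up(fraction * members.size)
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(members, size=k, replace=False).tolist())
    keep = np.array([j for j in range(matrix.n_characters) if j not in drop])
    return matrix.subset_columns(keep)


def mask_fossil_cells(
    matrix: CharacterMatrix, tree: Tree, fraction: float, seed: int | None = None
) -> CharacterMatrix:
    """Set a random fraction of each fossil taxon's cells to missing.

    For every leaf flagged fossil in ``tree``, ``round_half_up(fraction *
    n_characters)`` uniformly random cells in that row become '?'.
    Non-fossil rows are untouched.  Rows are located by label.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if not tree.fossil_labels:
        raise ValueError("tree has no fossil taxa flagged")
    missing_labels = tree.fossil_labels - set(matrix.taxa)
    if missing_labels:
        raise ValueError(f"fossil taxa absent from matrix: {sorted(missing_labels)}")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    k = _round_half_up(fraction * matrix.n_characters)
    for label in sorted(tree.fossil_labels):
        cols = rng.choice(matrix.n_characters, size=k, replace=False)
        out.data[out.taxa.index(label), cols] = MISSING
    return out
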