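"""Factorial simulation experiments: simulate binary characters on a model
tree, estimate trees with Bayesian Mk MCMC and with equal-weights
parsimony, and score every estimate against the truth by rescaled
Robinson-Foulds error.

The factors are the mean evolutionary rate (expected changes per
character over the whole tree), the rate mode (one shared rate vs
independent per-character gamma rates), the data-set size, the character
filtration (acquisition) scheme with its matching likelihood correction,
and structured missing data (rate-class deletion or fossil-cell
masking).  Every condition-replicate is fully determined by the config
plus the replicate index, so any record can be reproduced in isolation.

Desk-scale defaults (20 taxa, 350 characters, short chains) keep the full
factorial structure of the original cluster-scale design (75 taxa,
350/1000 characters) while running on a single CPU in minutes.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mk, simulate, trees
from .mcmc import McmcConfig, run_mcmc, split_frequency_agreement, summarize_posterior
from .parsimony import ParsimonySearchConfig, score_solution_set, tbr_search

__all__ = [
    "ExperimentConfig",
    "ResultRecord",
    "run_condition",
    "run_experiment",
    "replicate_figure",
    "summarize_results",
    "FIGURE_KEYS",
]

#: filtration scheme -> matching likelihood correction
ASCERTAINMENT_FOR_SCHEME = {
    "unfiltered": "none",
    "variable_only": "variable",
    "parsimony_informative_only": "parsimony_informative",
}

FIGURE_KEYS = ("fig3", "fig4", "fig5", "fig6", "figS1", "figS2")

#: fields of ExperimentConfig that a condition dict may override
_CONDITION_FIELDS = (
    "mean_rate", "rate_mode", "sim_gamma_shape", "n_characters", "filtration",
    "ascertainment", "fossil_mask_fraction", "delete_class", "delete_fraction",
    "methods",
)


@dataclass
class ExperimentConfig:
    """Study-level settings; condition dicts override per-condition factors."""

    # model tree (generated unless tree_newick is given)
    n_taxa: int = 20
    tree_newick: str | None = None
    fossil_fraction: float = 0.2
    total_length: float = 1.0
    short_branch_bias: float = 2.0
    tree_seed: int = 20140 % (2**31)

    # simulation factors (defaults; conditions override)
    n_characters: int = 350
    rate_grid: tuple = (0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0)
    mean_rate: float = 1.0
    rate_mode: str = "single"
    sim_gamma_shape: float | None = None  # None: exact rate in single mode
    filtration: str = "variable_only"
    ascertainment: str | None = None  # None: match the filtration scheme
    fossil_mask_fraction: float = 0.0
    delete_class: str | None = None
    delete_fraction: float = 0.0

    # estimation
    methods: tuple = ("bayes", "parsimony")
    inference_gamma_shape: float | None = None  # None: gamma iff per_character
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(
        n_generations=12000, sample_every=60))
    parsimony_search: ParsimonySearchConfig = field(
        default_factory=lambda: ParsimonySearchConfig(n_replicates=3))
    convergence_chains: int = 1  # 2 adds a second seed + agreement diagnostic

    # replication
    n_replicates: int = 10
    base_seed: int = 1


@dataclass
class ResultRecord:
    """One (condition, method, replicate) outcome."""

    method: str
    replicate: int
    n_taxa: int
    n_characters_simulated: int
    n_characters_analyzed: int
    mean_rate: float
    rate_mode: str
    filtration: str
    ascertainment: str
    fossil_mask_fraction: float
    delete_class: str | None
    delete_fraction: float
    rf: float
    rescaled_error_pct: float
    consensus_rf: float
    consensus_rescaled_error_pct: float
    score: float  # mean posterior lnL (bayes) or best parsimony score
    n_trees: int  # posterior sample size or equally-optimal set size
    convergence: float
    walltime_s: float
    status: str = "ok"
    error: str = ""


def _condition_config(config: ExperimentConfig, condition: Mapping) -> ExperimentConfig:
    unknown = set(condition) - set(_CONDITION_FIELDS)
    if unknown:
        raise ValueError(f"unknown condition fields: {sorted(unknown)}")
    return replace(config, **dict(condition))


def _model_tree(config: ExperimentConfig) -> trees.Tree:
    if config.tree_newick is not None:
        tree = trees.parse_newick(config.tree_newick)
        tree.validate(require_binary=True, require_lengths=True)
        if not tree.fossil_labels and config.fossil_fraction > 0:
            n = int(np.ceil(config.fossil_fraction * tree.n_leaves))
            ranked = sorted(tree.leaves(), key=lambda l: (l.length, l.label))
            tree.fossil_labels = frozenset(l.label for l in ranked[:n])
        return tree
    return simulate.generate_model_tree(
        n_taxa=config.n_taxa,
        fossil_fraction=config.fossil_fraction,
        total_length=config.total_length,
        short_branch_bias=config.short_branch_bias,
        seed=config.tree_seed,
    )


def _seeds(config: ExperimentConfig, condition: Mapping, replicate: int, n: int) -> list[int]:
    key = json.dumps(dict(condition), sort_keys=True, default=str)
    digest = zlib.crc32(key.encode()) % (2**31)
    ss = np.random.SeedSequence([config.base_seed, digest, replicate])
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) >> 1]


def run_condition(
    config: ExperimentConfig, condition: Mapping, replicate: int
) -> list[ResultRecord]:
    """Simulate -> filter -> inject missing data -> estimate -> score.

    Returns one record per requested method.  Estimation failures yield a
    record with status "error" and the pipeline continues.
    """
    cond = _condition_config(config, condition)
    tree = _model_tree(cond)
    n_taxa = tree.n_leaves
    seed_sim, seed_del, seed_mask, seed_bayes, seed_pars, seed_conv = _seeds(
        config, condition, replicate, 6)

    sim_config = simulate.SimulationConfig(
        n_characters=cond.n_characters,
        rate_mode=cond.rate_mode,
        gamma_shape=cond.sim_gamma_shape,
        mean_rate=cond.mean_rate,
        seed=seed_sim,
    )
    matrix = simulate.simulate_characters(tree, sim_config)
    if cond.delete_class is not None and cond.delete_fraction > 0:
        matrix = simulate.delete_rate_class(
            matrix, cond.delete_class, cond.delete_fraction, seed=seed_del)
    matrix = simulate.filter_matrix(matrix, cond.filtration)
    if cond.fossil_mask_fraction > 0:
        matrix = simulate.mask_fossil_cells(
            matrix, tree, cond.fossil_mask_fraction, seed=seed_mask)

    ascertainment = cond.ascertainment or ASCERTAINMENT_FOR_SCHEME[cond.filtration]
    if cond.inference_gamma_shape is not None:
        gamma_shape = cond.inference_gamma_shape
    else:
        gamma_shape = 1.0 if cond.rate_mode == "per_character" else None

    base = dict(
        replicate=replicate,
        n_taxa=n_taxa,
        n_characters_simulated=cond.n_characters,
        n_characters_analyzed=matrix.n_characters,
        mean_rate=cond.mean_rate,
        rate_mode=cond.rate_mode,
        filtration=cond.filtration,
        ascertainment=ascertainment,
        fossil_mask_fraction=cond.fossil_mask_fraction,
        delete_class=cond.delete_class,
        delete_fraction=cond.delete_fraction,
    )
    records = []
    for method in cond.methods:
        t0 = time.perf_counter()
        try:
            if method == "bayes":
                rec = _run_bayes(cond, matrix, tree, ascertainment, gamma_shape,
                                 seed_bayes, seed_conv, base)
            elif method == "parsimony":
                rec = _run_parsimony(cond, matrix, tree, seed_pars, base)
            else:
                raise ValueError(f"unknown method {method!r}")
            rec.walltime_s = time.perf_counter() - t0
        except Exception as exc:  # keep the batch running
            rec = ResultRecord(method=method, rf=np.nan, rescaled_error_pct=np.nan,
                               consensus_rf=np.nan, consensus_rescaled_error_pct=np.nan,
                               score=np.nan, n_trees=0, convergence=np.nan,
                               walltime_s=time.perf_counter() - t0,
                               status="error", error=str(exc), **base)
        records.append(rec)
    return records


def _rescale(rf: float, n_taxa: int) -> float:
    return 100.0 * rf / trees.max_rf(n_taxa)


def _run_bayes(cond, matrix, tree, ascertainment, gamma_shape,
               seed, seed_conv, base) -> ResultRecord:
    params = mk.MkParams(ascertainment_mode=ascertainment, gamma_shape=gamma_shape)
    mcmc_config = replace(cond.mcmc, seed=seed)
    sample = run_mcmc(matrix, params, mcmc_config)
    consensus, _freqs = summarize_posterior(sample)
    rf = trees.rf_distance(consensus, tree)
    retained = sample.records[int(len(sample.records) * mcmc_config.burnin_fraction):]
    convergence = np.nan
    if cond.convergence_chains > 1:
        other = run_mcmc(matrix, params, replace(cond.mcmc, seed=seed_conv))
        convergence = split_frequency_agreement(sample, other)
    return ResultRecord(
        method="bayes", rf=float(rf), rescaled_error_pct=_rescale(rf, base["n_taxa"]),
        consensus_rf=float(rf), consensus_rescaled_error_pct=_rescale(rf, base["n_taxa"]),
        score=float(np.mean([r.log_likelihood for r in retained])),
        n_trees=len(retained), convergence=convergence, walltime_s=np.nan, **base)


def _run_parsimony(cond, matrix, tree, seed, base) -> ResultRecord:
    search = replace(cond.parsimony_search, seed=seed)
    solutions, best = tbr_search(matrix, search)
    mean_rf, cons_rf = score_solution_set(solutions, tree)
    return ResultRecord(
        method="parsimony", rf=mean_rf, rescaled_error_pct=_rescale(mean_rf, base["n_taxa"]),
        consensus_rf=float(cons_rf),
        consensus_rescaled_error_pct=_rescale(cons_rf, base["n_taxa"]),
        score=float(best), n_trees=len(solutions), convergence=np.nan,
        walltime_s=np.nan, **base)


def run_experiment(
    config: ExperimentConfig, conditions: Sequence[Mapping]
) -> pd.DataFrame:
    """Run every (condition, replicate) and return one tidy row per record."""
    rows = []
    for condition in conditions:
        for replicate in range(config.n_replicates):
            for rec in run_condition(config, condition, replicate):
                rows.append(vars(rec))
    return pd.DataFrame(rows)


def summarize_results(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd rescaled error per condition per method."""
    keys = ["method", "mean_rate", "rate_mode", "n_characters_simulated",
            "filtration", "fossil_mask_fraction", "delete_class", "delete_fraction"]
    grouped = (
        results[results.status == "ok"]
        .groupby(keys, dropna=False)["rescaled_error_pct"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_error_pct", "std": "sd_error_pct",
                         "count": "n_replicates"})
    )
    return grouped


# ---------------------------------------------------------------------------
# figure presets (reduced-scale condition grids)
# ---------------------------------------------------------------------------


def _figure_conditions(config: ExperimentConfig, figure: str) -> list[dict]:
    grid = list(config.rate_grid)
    if figure == "fig3":
        return [{"mean_rate": r, "fossil_mask_fraction": f}
                for f in (0.0, 0.75) for r in grid]
    if figure == "fig4":
        return [{"mean_rate": r, "rate_mode": "per_character", "sim_gamma_shape": 1.0}
                for r in grid]
    if figure == "fig5":
        base = {"rate_mode": "per_character", "sim_gamma_shape": 1.0,
                "mean_rate": config.mean_rate}
        out = [dict(base)]
        out += [dict(base, delete_class=c, delete_fraction=1 / 3)
                for c in simulate.RATE_CLASSES]
        return out
    if figure == "fig6":
        return [{"mean_rate": r, "n_characters": n}
                for n in (350, 1000) for r in (0.5, 1.0, 2.0)]
    if figure == "figS1":
        return [{"mean_rate": config.mean_rate, "filtration": f}
                for f in simulate.FILTRATION_SCHEMES]
    if figure == "figS2":
        return [{"mean_rate": r, "methods": ("parsimony",)} for r in grid]
    raise ValueError(f"unknown figure key {figure!r}; use one of {FIGURE_KEYS}")


def replicate_figure(
    config: ExperimentConfig | None, figure: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the condition grid behind one comparison figure.

    Returns (per-replicate tidy results, mean +/- sd summary) — enough to
    redraw the figure's comparison at the configured scale.
    """
    if config is None:
        config = ExperimentConfig()
    conditions = _figure_conditions(config, figure)
    results = run_experiment(config, conditions)
    return results, summarize_results(results)
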