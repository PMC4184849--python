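# mkphylo

Simulation machinery for asking a practical question in morphological
phylogenetics: **when should a paleontologist trust Bayesian inference
under the Mk model over equal-weights parsimony?**

Discrete morphological matrices are small (a few hundred binary
characters), observer-filtered (invariant and autapomorphic characters
are rarely scored), rate-heterogeneous, and riddled with missing data
concentrated in fossil taxa.  `mkphylo` simulates exactly this kind of
data on a model tree with many short branches, estimates trees with both
a Bayesian Mk sampler and a TBR parsimony search, and scores every
estimate against the truth with the rescaled Robinson–Foulds distance —
so the whole accuracy comparison runs on one CPU in minutes.

## The model

Characters evolve under the binary Mk model, the two-state symmetric
continuous-time Markov process (a relabelling of the Jukes–Cantor model):
stationary frequencies (½, ½) and transition probabilities

    P(same | t)      = ½ + ½ e^(−2t)
    P(different | t) = ½ − ½ e^(−2t)

with branch length *t* in expected changes.  A character's rate *r* is
parameterized as expected changes summed over the whole tree, so *r* = 1
means one expected change per character.  Among-character rate variation
is gamma-distributed (discrete-gamma with 4 equi-probable categories on
the inference side).

Acquisition bias is handled by conditioning: when only variable
characters are collected, each site likelihood is divided by
1 − P(invariant pattern) (the **Mkv** correction); when only
parsimony-informative characters are collected, the 2N autapomorphic
patterns are excluded as well (**Mk-pars**).  For binary states both
corrections are computed exactly by summing the dummy patterns.

Topological error between an estimate and the model tree is the
unweighted Robinson–Foulds symmetric distance, rescaled by its maximum
2(N − 3); for 75 taxa, 144 distance units = 100% error.  Bayesian runs
are scored through the majority-rule consensus of the posterior sample;
parsimony runs through both the average over the equally-optimal set and
the consensus of that set.

## Worked example

```python
import mkphylo as mp

tree = mp.generate_model_tree(n_taxa=20, seed=5)        # short-branch model tree
matrix = mp.simulate_characters(tree, mp.SimulationConfig(
    n_characters=350, rate_mode="single", gamma_shape=None,
    mean_rate=1.0, seed=7))                              # one expected change/char
variable = mp.filter_matrix(matrix, "variable_only")     # observer filtering

sample = mp.run_mcmc(variable, mp.MkParams(ascertainment_mode="variable"),
                     mp.McmcConfig(n_generations=12000, sample_every=60, seed=3))
consensus, freqs = mp.summarize_posterior(sample)
rf = mp.rf_distance(consensus, tree)
print(rf, mp.rescaled_error(rf, 20))

solutions, best = mp.tbr_search(variable, mp.ParsimonySearchConfig(
    n_replicates=3, seed=1))
mean_rf, cons_rf = mp.score_solution_set(solutions, tree)
print(best, len(solutions), mean_rf)
```

printing

```
2 5.882352941176471
301 4 2.0
```

— the Bayesian consensus misses 2 of the 34 scorable bipartition slots
(5.9% rescaled error; the unrecovered splits sit on branches carrying
less than one expected change across the whole matrix), while the
parsimony search finds 4 equally optimal trees of score 301 averaging
symmetric distance 2 from the truth.

Grid experiments are one call (or `mkphylo figure fig3 --out results.tsv`
from the shell):

```python
results, summary = mp.replicate_figure(mp.ExperimentConfig(n_replicates=10), "fig3")
```

which returns one tidy row per (rate, missing-data level, method,
replicate) with raw and rescaled errors.

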