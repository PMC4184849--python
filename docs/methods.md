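# Methods

This note documents the models, algorithms, defaults, and design choices
behind `mkphylo`, and what its desk-scale simulations do and do not show.

## The evolutionary model

Characters are binary and evolve independently under the two-state Mk
process: symmetric instantaneous rates, stationary frequencies (½, ½),
rate matrix normalized so a branch of length *t* expects *t* changes.
The closed-form transition probabilities are
P(same | t) = ½ + ½e^(−2t) and P(diff | t) = ½ − ½e^(−2t).

**Rate parameterization.** A character's rate *r* is its expected number
of changes summed over the whole tree; the effective length of branch
*b* for that character is `length(b) · r / total_tree_length`.  This
makes the experimental rate axis directly interpretable ("one expected
change per character" ⇔ *r* = 1) and makes the absolute scale of the
model tree irrelevant to simulation — only relative branch lengths
matter.

**Rate heterogeneity.** In `per_character` mode each character draws its
rate from a gamma with mean `mean_rate` and shape `gamma_shape`
(default 1.0, i.e. exponential: a strongly heterogeneous but standard
default; no canonical value exists for morphological data, so the shape
is exposed and recorded in outputs).  In `single` mode all characters
share one rate — itself a gamma draw when a shape is given, or exactly
`mean_rate` when `gamma_shape=None`.  The exact option exists because
grid experiments need the x-axis rate to be the realized rate;
experiment presets use it.

## The model tree

`generate_model_tree` builds a rooted binary topology by uniform random
edge attachment and draws branch lengths as Uniform(0,1)^bias rescaled
to `total_length`.  The default `short_branch_bias = 2.0` gives a
density ∝ x^(−1/2): most branches short, a few long, with the shortest
internal branches carrying well under one expected change per matrix at
*r* = 1 — emulating the hard, fossil-rich empirical regime (many short
internodes) without producing numerically zero branches.  A fraction of
leaves (default 20%) is flagged "fossil"; by default the leaves with the
shortest terminal branches, since fossil taxa typically attach on short
terminal branches, with a random-flagging option.  Any user-supplied
rooted binary newick tree can be substituted.

## Filtration and ascertainment corrections

Columns are classified from their non-missing cells: invariant (≤ 1
state observed; an all-missing column is a degenerate invariant, kept
classifiable so batch pipelines do not die), autapomorphic (variable but
one state occurs once), or parsimony-informative (both states ≥ 2).
Filtration schemes drop the excluded classes, preserving column order
and the alignment of the true-rate vector.

The matching likelihood corrections condition each site on being
observable: the site likelihood is divided by 1 − P(excluded patterns),
where the excluded mass is computed exactly by pruning the 2 constant
patterns (variable-only conditioning) or the 2 constant plus 2N
singleton patterns (parsimony-informative conditioning).  Applying a
correction to data that violates its sampling assumption is permitted
with a warning (misspecification is exposed, not studied).

## Missing data

Two structured schemes, mirroring how incompleteness arises in practice:

* **Rate-class deletion** sorts characters by their true simulating rate
  into slow/intermediate/fast tertiles (sizes differ by ≤ 1, earlier
  classes take the remainder; ties broken by column index) and removes a
  random `round_half_up(fraction · class_size)` subset of one class.
  True rates are used because they are known in simulation; estimating
  them would conflate measurement error with the treatment.
* **Fossil-cell masking** sets `round_half_up(fraction · n_characters)`
  uniformly random cells to `?` in every fossil row.

Round-half-up and earlier-class-remainders are arbitrary conventions,
fixed and documented so counts are exactly reproducible.  Rows are
always addressed by taxon label, so both operations commute with taxon
reordering.

## Likelihood machinery

Felsenstein pruning over site patterns (columns are compressed to unique
patterns first), with missing tips contributing (1, 1) partials,
stationary (½, ½) root frequencies, and periodic per-node rescaling with
a log-scale accumulator so low-rate or large-tree likelihoods do not
underflow.  Discrete-gamma heterogeneity uses equi-probable categories
with mean-of-category rates (category means computed from the regularized
incomplete gamma; they average exactly 1); the site likelihood averages
the conditional likelihoods over categories.  Exhaustive
state-enumeration oracles in the test suite pin the pruning kernel, the
ascertainment corrections (conditional pattern distributions sum to 1),
and root-placement invariance.

## Bayesian sampler

A single cold Metropolis–Hastings chain over (topology, branch lengths,
gamma shape).  Priors: uniform over fully resolved unrooted topologies,
i.i.d. exponential branch lengths (default mean 0.1), exponential shape
prior (mean 1.0).  The state is stored as a rooted tree; the likelihood
is root-invariant and every unrooted topology has the same number of
rooted forms, so the rooted-uniform target marginalizes to the unrooted
uniform prior.

Moves and their Hastings ratios:

* **NNI** — swap a uniformly chosen child of a non-root internal node
  with that node's sibling.  Every topology has exactly 2(N − 2) such
  moves, each self-inverse: symmetric.
* **Subtree exchange** — swap two subtrees whose roots are neither
  nested nor siblings, stems travelling with the subtrees.  The
  candidate-pair count depends on the topology, so the ratio is
  n_pairs(current)/n_pairs(proposed).  This is the wide-jump move: a
  classical SPR with branch merging/splitting would change the
  branch-length dimension pairing and require a Green-type Jacobian;
  the exchange achieves comparable mixing with none of that machinery
  and leaves the branch-length set (hence the prior) untouched.
* **Branch multiplier** — t′ = t·e^(λ(u−½)) on one branch (ratio t′/t).
* **Tree-scale** — the same multiplier on every branch simultaneously
  (ratio c^n_edges).  Essential when the data demand a tree length far
  from the starting state's (e.g. high-rate data: tree length ≈ 10);
  single-branch multipliers alone adapt far too slowly.
* **Shape multiplier** — on the gamma shape, active only under the
  heterogeneous model.

Default tuning λ = 1.4 gives single-branch acceptance ≈ 0.6–0.7 and
NNI ≈ 0.15–0.25 on 20-taxon problems.  Chains on data start from a
random-addition parsimony tree (branch lengths redrawn from the prior) —
a neutral, data-informed start that removes most burn-in at desk scale;
prior-only validation uses uniform random starts.  Prior-only mode
(likelihood ≡ 1) is used to verify the sampler against its own priors:
uniform topology frequencies, exponential branch lengths, exponential
shape.  A two-seed split-frequency agreement diagnostic
(`split_frequency_agreement`, max |Δfreq|, < 0.05 is conventionally
"converged") is available and exercised in the tests; experiment presets
run one chain per replicate to stay inside desk-scale budgets.

The posterior is summarized by the strict majority-rule consensus
(splits with frequency > 0.5; exactly-50% ties excluded), which can be
unresolved — unresolved true splits count as errors under unweighted RF,
the conventional reading of the symmetric distance.

## Parsimony engine

Fitch scoring with `?` as the full state set.  Search: random-addition
starting trees (taxa shuffled, each placed on the Fitch-minimal branch,
ties uniform) followed by first-improvement TBR hill-climbing with
seeded random neighbor order, pooling all distinct equally-optimal
topologies across replicates (deduplicated by bipartition set, capped at
`max_trees_retained`, truncation warned).

TBR neighbors are scored incrementally: for each bisection, one up-pass
and one down-pass per fragment yield the Fitch state set a virtual root
would carry on every branch; the score of any reconnection is then
score(A) + score(B) + #characters with disjoint root sets, using the
root-invariance of the Fitch count.  A test compares every incremental
neighbor score against full re-scoring, and the search is checked
against exhaustive enumeration of all 945 seven-taxon topologies.

Solution sets are scored both ways used in practice — mean RF over the
set and RF of its majority-rule consensus — and the experiment records
both.

## Experiments and desk-scale defaults

`run_condition` composes simulate → delete/filter/mask → estimate →
score, one record per method, with every random stage seeded from
(base_seed, condition-hash, replicate) so any record reproduces in
isolation; estimation failures become `status="error"` records rather
than aborting the batch.

Default problem sizes are chosen for a single CPU: 20 taxa, 350
characters (1000 available), rate grid {0.1, 0.25, 0.5, 1, 2, 5, 10}
expected changes per character, 10 replicates per condition, MCMC
12 000 generations sampled every 60 with 25% burn-in, parsimony 3
random-addition replicates.  Full-scale settings (75 taxa, 1000
replicates of random addition, long chains) are plain config values.
Figure presets (`fig3`–`fig6`, `figS1`, `figS2`) reproduce the factorial
structure of the headline comparisons: single-rate grid ± fossil
masking, heterogeneous-rate grid, rate-class deletion, 350 vs 1000
characters, the three filtration/correction pairs, and
mean-vs-consensus parsimony scoring.

## What the synthetic data does and does not capture

Emulated: binary characters, observer filtration, gamma rate
heterogeneity, short-branch-dominated trees, missing data concentrated
in fossil taxa or rate classes.  Not emulated: multistate characters,
correlated characters, non-stationary or asymmetric processes, real
morphological character covariation, and the specific topology of any
empirical tree.  Passing tests therefore demonstrate correctness of the
machinery and the direction of method differences under the stated
generative model — not quantitative error rates for any real data set.

At 20 taxa × 350 characters, each internal branch is informed by roughly
four times as many characters per branch as a 75-taxon matrix of the
same size, so absolute errors run lower than full-scale analyses and the
rate at which error is minimized can sit a grid step away from its
full-scale position; the direction of the comparisons (Bayesian ≤
parsimony error, sharpest at high rates; equivalence of matched
corrections; agreement of the two parsimony scorings) is the stable,
transferable content.

## Numerical and degenerate-input policy

Branch lengths must be non-negative; likelihood requires lengths on all
edges.  Zero-length trees make the variable-only correction divide by
zero probability mass (excluded mass 1); this raises a "degenerate tree"
error.  Empty matrices: parsimony scores 0 with a warning; MCMC requires
prior-only mode.  All-`?` columns have likelihood exactly 1 and Fitch
score 0.  Filtration may empty a matrix (warning, not error).  RNG is
`numpy.random.default_rng` throughout; every public stochastic operation
takes an explicit seed and is bit-reproducible under it.
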