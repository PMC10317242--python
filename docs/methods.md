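# Methods

This note documents the model implemented by `feddna`, the conventions
chosen where the procedure leaves details open, what the synthetic data
does and does not emulate, and the numerical choices that matter for
reproducing results.

## Matching model

A neuron of hidden layer `l` is represented by its incoming-weight vector
(length = input dimension of the layer). Bias inclusion is available as a
flag at the distance-source level but excluded by default: the node
identity we want to compare is the feature pattern a unit responds to.
Distances are Euclidean or Manhattan; both satisfy the metric axioms
(property-tested).

**Greedy tree growth.** A matching tree holds at most one neuron per site.
Growth repeatedly evaluates every unmatched neuron of every unmatched site
against the tree and joins the argmin; the joined site leaves the pool.
Node-to-tree distance comes in three anchor modes:

- `all_members` — minimum over current members (the full dynamic method);
- `seed_only` — distance to the tree's first member (fixed-anchor baseline);
- `random_member` — distance to one member drawn uniformly per growth step
  (random-anchor baseline).

**Seeding.** Two modes, because the procedure is described both ways:
`random` seeds each tree from a random unmatched site and node (the default
protocol); `global_min` seeds from the globally closest remaining
cross-site pair, which is the deterministic variant that reproduces the
three-site worked example. All ties break on lowest (site, node) index, so
runs are reproducible given the seed.

**Matching cost.** The reported scalar is the sum over trees of their join
distances. For groupings produced without a recorded growth (the static
index grouping, the exhaustive oracle) the joins are replayed from each
tree's lowest-site member, always joining the nearest remaining member;
this replay yields the minimum-spanning-tree weight of the group, is
invariant to member order, and coincides exactly with what greedy growth
records under the `all_members` anchor. That identity is what makes the
oracle bound (greedy cost ≥ exhaustive optimum) a theorem rather than an
empirical observation, since the oracle minimizes the same functional.

**Exhaustive oracle.** `optimal_matching` enumerates all `(n!)^(Σ-1)`
groupings and is guarded at Σ ≤ 4, n ≤ 6; it exists to bound the greedy
matcher in tests, never as an alternative alignment path.

**Complexity.** Pairwise distances are memoized, so the matcher performs at
most one vector-distance evaluation per unordered cross-site node pair:
≤ Σ(Σ−1)/2 · n² evaluations of cost `m` each. Treating the node-to-tree
lookup as a single evaluation gives the conventional Σ·n²·m accounting; the
literal all-members count carries the extra (Σ−1)/2 factor, which is a
small constant for the federation sizes this method targets (≤ ~7 sites;
the reference protocol uses 5). Tests assert the bound `2·Σ·n²` on unique
evaluations for Σ ∈ {2..6} together with quadratic growth in `n`.

## Local model and training

Dense network `input → hidden … → 1`, ReLU hidden activations, sigmoid
output, mean binary cross-entropy loss, plain mini-batch SGD
(`w ← w − η ∇l(w; b)`). Activations and loss are conventions (the update
protocol prescribes only plain SGD); they are the standard choice for small
tabular binary classifiers. Defaults: hidden sizes (10, 8), batch size 32,
2 local epochs per round, learning rate 0.1, Glorot-uniform initialization
fully determined by a seed. Gradients are validated against central finite
differences (relative tolerance 1e-4; the ReLU subgradient at 0 is taken
as 0, and test points avoid kinks with probability 1).

"Training to convergence" for replicate runs means: stop when the
full-data epoch loss has improved by less than 1e-4 for 3 consecutive
epochs, with a hard cap (default 200 epochs; the variance diagnostic uses
150 — ample for the 500-sample tables it trains on).

## Federated loop and dispatch

Each round: local SGD on every client → aggregation → dispatch of the
global weights to all clients. During the first `freeze_rounds` rounds an
alignment variant matches the configured hidden layer across clients and
every client's layer is *permuted* so matched neurons share an index (rows,
biases, and next-layer columns move together — a function-preserving
operation). Afterwards matching is frozen and plain index-wise FedAvg
continues; because dispatch already placed matched neurons at common
indices, the frozen phase averages genuinely aligned units. Matching is
recomputed each round within the dynamic phase.

Aggregation weighting: non-matched layers use sample-count coefficients
`n_k/n`; the matched layer uses the plain per-tree mean (tree members count
equally), with a flag to force `n_k` weighting everywhere. The round
history records the matching cost of aligned rounds and, as a diagnostic,
the cost of the static index grouping on the same trained client weights.

Floating-point note: permutation dispatch reorders summations inside dot
products, so "unchanged" outputs agree to ~1 ulp (measured max 2.2e-16),
not bitwise; tests assert agreement at atol 1e-12.

## Synthetic data

The generator draws a two-class Gaussian mixture: an `informative_fraction`
of features has a class-mean gap of `class_separation · noise_sd`, the rest
are pure noise; the negative:positive label ratio is realized exactly after
rounding. Defaults (chosen once as a plausible stand-in for small clinical
tabular benchmarks): 10 features matching the 10-unit motivating
architecture, separation 2.0, noise sd 1.0, informative fraction 0.5,
balanced classes. Non-IID conditions are produced by class-ratio
downsampling, random partitioning into K sites, and a two-client exchange
that swaps 2/3 of two random sites' samples.

The benchmark condition (`run_alignment_benchmark`) additionally permutes
each client's copy of the shared initial hidden layer. This *plants* the
permutation ambiguity that index-wise averaging cannot see; it emulates the
end state of clients that converged to permuted optima without requiring
long divergent training. What passing these tests shows is that the
matcher recovers planted or emergent neuron correspondences and that
aligned aggregation does not lose accuracy relative to FedAvg under these
conditions; it does not show that alignment improves accuracy on any
particular real clinical dataset, where feature correlations, label noise
and covariate shift are richer than the mixture model.

Problem sizes: the variance diagnostic trains 5 replicates on 500-sample
tables, 10 repetitions; the federated benchmark uses 1000 training / 400
test samples, 5 clients, 10 rounds, freeze after 2, over 10 seeds. These
sizes give stable orderings of the compared quantities while keeping the
full suite in single-digit minutes on one CPU.

## Evaluation

Accuracy, F1 (positive class) and balanced accuracy at threshold 0.5, AUC
as the rank statistic, loss as mean binary cross-entropy (computed via
scikit-learn; cross-checked in tests against hand-computed confusion-count
and Mann–Whitney formulas). AUC is reported as NaN when the evaluation
split contains a single class. Cross-validation is stratified K-fold with
folds and federated rounds as independent knobs (both default 10); min-max
feature scaling is fitted on each training fold only. Within a fold every
method starts from the same shared initialization.

The replicate variance diagnostic reports, per node and per input
dimension, the sample variance (ddof = 1) of weights across replicates —
grouped either by node index (static) or by matched trees after aligning
the replicates as if they were sites (dynamic).

## Known limitations

- Alignment is implemented for one dense hidden layer at a time of
  identically shaped networks; no cross-architecture or convolutional
  matching.
- Binary classification only (single sigmoid head).
- The exhaustive oracle is intractable beyond its small-instance guard —
  by design.
- Greedy matching carries no optimality guarantee; the oracle bound tests
  quantify (and the benchmark exploits) its behaviour only at small scale.
- The simulator runs in-process; there is no transport, encryption,
  client sampling, or dropout handling.
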