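# feddna — federated learning with dynamic neuron alignment

A tested simulator of **alignment-aware federated averaging** for dense
binary classifiers, aimed at federated settings common in healthcare
prediction (several sites, private tabular data, non-IID class mixes).

## The problem and the method

In federated learning, `Σ` clients train local copies of a shared network
and a server aggregates their weights each round. Standard FedAvg averages
*index-wise*:

```
w_{t+1} = Σ_k (n_k / n) · w_t^k
```

But hidden units of a dense network are permutation-symmetric: two clients
can implement near-identical functions with their neurons in different
orders, so averaging neuron `i` of every client mixes unrelated units.

This package implements **dynamic node alignment**: each neuron is
represented by its incoming-weight vector `v_i^α = [w_{i,0}^α, …, w_{i,m}^α]`,
cross-site similarity is measured by Euclidean or Manhattan distance, and
neurons are grouped by greedily growing a minimum-spanning-tree-style
*matching tree* `T` — one neuron per site — always joining the candidate
`v*` minimizing the node-to-tree distance

```
d(v, T) = min_{u ∈ T} d(v, u)
```

Repeating until every neuron is matched partitions the layer into `n`
complete trees. Matched neurons are permuted to a common index
(function-preserving), averaged per tree, and dispatched back. Alignment
runs for the first `i` rounds, then the matching is *frozen* and plain
FedAvg continues on the aligned indices. Greedy growth needs on the order
of `Σ·n²·m` distance work versus the `n^Σ·m` of exhaustive optimal
matching (which is included as a small-instance test oracle).

Baseline variants: `static` (FedAvg), `fixed` (distances to the tree seed
only), `random` (distance to one random tree member), `plain` (pooled,
non-federated training).

## Worked example

Three sites with three neurons each, given only their printed cross-site
distance blocks (`feddna.worked_example`). With global-minimum seeding the
matcher seeds the first tree with the closest pair (B, a) at 0.11, then
admits Site 3's `alpha` at 0.13:

```
$ feddna match --example --seeding global_min --out matching.json
INFO feddna: matched 3 sites x 3 nodes, total cost 0.930000 -> matching.json
```

with `matching.json` containing the first tree

```json
{"members": [[0, 1], [1, 0], [2, 0]], "join_distances": [0.11, 0.13]}
```

i.e. the group {B, a, alpha}; the remaining six neurons form two more
complete trees ({C, b, beta}, {A, c, gamma}) for a total matching cost
0.11 + 0.13 + 0.14 + 0.18 + 0.16 + 0.21 = 0.93.

A full federated run on the synthetic non-IID benchmark (5 clients, two of
which exchanged 2/3 of their data; each client's copy of the shared
initialization hidden-permuted; 10 rounds, alignment frozen after 2,
Manhattan distance):

```python
from feddna.experiment import run_alignment_benchmark
hist = run_alignment_benchmark(seed=0)
r0 = hist["dynamic"][0]
print(r0.matching_cost, r0.static_cost)   # 0.9212 vs 107.7355
print(hist["dynamic"][-1].metrics.accuracy)  # 0.9800
print(hist["static"][-1].metrics.accuracy)   # 0.9775
```

In round 0 the dynamic matching finds neuron groups with total distance
~0.92 where the static index grouping of the same trained clients scores
~108 (the planted permutations); FedAvg's round-0 global model drops to
chance accuracy (0.50) while the aligned aggregate starts at 0.67 and both
recover over later rounds.

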