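"""The federated loop: local SGD, alignment-aware aggregation, dispatch.

Each round, every client trains the current global weights on its own data;
the server then aggregates.  Under *static* aggregation (FedAvg) weights are
averaged index-wise with sample-count coefficients n_k/n.  Under an
*alignment* variant the chosen hidden layer is first matched across clients
(full dynamic tree matching, fixed seed anchor, or random member anchor),
every client's layer is permuted so matched neurons share an index — a
function-preserving operation — and the matched layer is averaged as a plain
per-tree mean while all other layers keep the n_k/n weighting.  Alignment
runs only during the first ``freeze_rounds`` rounds; afterwards matching is
frozen and plain FedAvg acts on the already-aligned indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .data import FederatedDataset, LabeledTable
from .matching import (
    MatchingResult,
    WeightDistanceSource,
    align_nodes,
    identity_matching,
    matching_cost,
)
from .metrics import MetricsReport, compute_metrics
from .network import (
    NetworkWeights,
    TrainingHyperparams,
    client_update,
    forward,
    init_network,
    layer_node_vectors,
    permute_hidden_units,
)

__all__ = [
    "ClientState",
    "GlobalState",
    "FLConfig",
    "RoundRecord",
    "VARIANTS",
    "fedavg_aggregate",
    "matched_layer_average",
    "apply_alignment",
    "federated_round",
    "run_federated",
    "records_to_frame",
]

VARIANTS = ("static", "dynamic", "fixed", "random", "plain")

#: alignment variant -> node-to-tree anchor mode
_VARIANT_ANCHOR = {
    "dynamic": "all_members",
    "fixed": "seed_only",
    "random": "random_member",
}


@dataclass
class ClientState:
    """One site: its identifier, current model, and local data."""

    site: int
    weights: NetworkWeights
    data: LabeledTable

    @property
    def n_samples(self) -> int:
        return self.data.n_samples


@dataclass
class GlobalState:
    """Server-side model and the current round index."""

    weights: NetworkWeights
    round: int = 0


@dataclass
class FLConfig:
    """Full configuration of one federated run.

    ``aligned_layer`` indexes hidden layers (0 = first hidden layer).
    ``freeze_rounds`` is the number of initial rounds with dynamic alignment;
    the remaining rounds use static averaging on the frozen node order.
    """

    clients: int = 5
    rounds: int = 10
    freeze_rounds: int = 2
    metric: str = "manhattan"
    variant: str = "dynamic"
    aligned_layer: int = 0
    seeding: str = "random"
    hidden_sizes: tuple[int, ...] = (10, 8)
    hyperparams: TrainingHyperparams = field(default_factory=TrainingHyperparams)
    seed: int = 0
    include_bias: bool = False
    force_sample_weighted: bool = False
    record_static_cost: bool = True

    def __post_init__(self) -> None:
        if self.clients < 1:
            raise ValueError("need at least one client")
        if not (0 <= self.freeze_rounds <= self.rounds):
            raise ValueError("freeze_rounds must satisfy 0 <= i <= rounds")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.aligned_layer >= len(self.hidden_sizes):
            raise ValueError("aligned_layer must index a hidden layer")

    @classmethod
    def from_dict(cls, d: dict) -> "FLConfig":
        d = dict(d)
        hp = d.pop("hyperparams", None)
        cfg = cls(**d)
        if hp is not None:
            cfg = replace(cfg, hyperparams=TrainingHyperparams(**hp))
        if "hidden_sizes" in d:
            cfg = replace(cfg, hidden_sizes=tuple(d["hidden_sizes"]))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "FLConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "clients": self.clients,
            "rounds": self.rounds,
            "freeze_rounds": self.freeze_rounds,
            "metric": self.metric,
            "variant": self.variant,
            "aligned_layer": self.aligned_layer,
            "seeding": self.seeding,
            "hidden_sizes": list(self.hidden_sizes),
            "hyperparams": {
                "batch_size": self.hyperparams.batch_size,
                "epochs": self.hyperparams.epochs,
                "learning_rate": self.hyperparams.learning_rate,
            },
            "seed": self.seed,
            "include_bias": self.include_bias,
            "force_sample_weighted": self.force_sample_weighted,
            "record_static_cost": self.record_static_cost,
        }


@dataclass
class RoundRecord:
    """Per-round history entry of a federated run.

    ``matching_cost`` is present exactly when an alignment variant ran that
    round; ``static_cost`` is the diagnostic cost of the identity grouping
    on the same trained client weights (recorded when enabled).
    """

    round: int
    variant: str
    matching_cost: float | None
    static_cost: float | None
    metrics: MetricsReport


def fedavg_aggregate(
    clients: Sequence[ClientState], sample_weighted: bool = True
) -> NetworkWeights:
    """Index-wise weighted average of client weights (coefficients n_k/n).

    With ``sample_weighted=False`` all clients count equally.  Coefficients
    always sum to 1, so aggregating identical clients returns their common
    weights unchanged.
    """
    if not clients:
        raise ValueError("need at least one client")
    arch = clients[0].weights.architecture
    for c in clients[1:]:
        if c.weights.architecture != arch:
            raise ValueError("client architectures differ")
    if sample_weighted:
        counts = np.array([c.n_samples for c in clients], dtype=float)
        coeff = counts / counts.sum()
    else:
        coeff = np.full(len(clients), 1.0 / len(clients))
    weights = [
        sum(a * c.weights.weights[l] for a, c in zip(coeff, clients))
        for l in range(len(arch) - 1)
    ]
    biases = [
        sum(a * c.weights.biases[l] for a, c in zip(coeff, clients))
        for l in range(len(arch) - 1)
    ]
    return NetworkWeights(weights, biases)


def matched_layer_average(
    matching: MatchingResult, clients: Sequence[ClientState], layer: int
) -> np.ndarray:
    """Per-tree plain mean of matched incoming-weight vectors.

    Row ``j`` of the result is the unweighted average of tree ``j``'s member
    vectors (tree members count equally; no sample-count weighting).
    """
    mats = [c.weights.weights[layer] for c in clients]
    site_of = {c.site: i for i, c in enumerate(clients)}
    n, m = mats[0].shape
    if matching.sites != len(clients) or matching.nodes_per_site != n:
        raise ValueError("matching shape inconsistent with clients' layer")
    out = np.empty((len(matching.trees), m))
    for j, tree in enumerate(matching.trees):
        out[j] = np.mean([mats[site_of[mm.site]][mm.node] for mm in tree.members], axis=0)
    return out


def apply_alignment(client: ClientState, matching: MatchingResult, layer: int) -> ClientState:
    """Reorder a client's aligned layer so tree members share tree indices.

    Permutes layer ``layer``'s rows and biases (and the next layer's input
    columns) so that the client's member of tree ``j`` sits at index ``j``.
    The client's input-output map is unchanged.
    """
    perm = matching.permutation_for_site(client.site)
    return replace(client, weights=permute_hidden_units(client.weights, layer, perm))


def _aggregate_aligned(
    clients: Sequence[ClientState], layer: int, force_sample_weighted: bool
) -> NetworkWeights:
    """Aggregate already-aligned clients: matched layer plain mean, rest n_k/n."""
    agg = fedavg_aggregate(clients, sample_weighted=True)
    if not force_sample_weighted:
        plain = fedavg_aggregate(clients, sample_weighted=False)
        agg.weights[layer] = plain.weights[layer]
        agg.biases[layer] = plain.biases[layer]
    return agg


def federated_round(
    global_state: GlobalState,
    clients: Sequence[ClientState],
    config: FLConfig,
    round_index: int,
    match_rng,
    train_rngs: Sequence,
):
    """One local-update / aggregate / dispatch cycle.

    Returns ``(new_global, new_clients, matching_cost, static_cost)``.
    Clients are assumed to hold the current global weights on entry; on exit
    every client holds the new global weights.
    """
    if len(train_rngs) != len(clients):
        raise ValueError("one training rng stream per client required")
    trained = [
        replace(c, weights=client_update(c.weights, c.data.X, c.data.y,
                                         config.hyperparams, rng))
        for c, rng in zip(clients, train_rngs)
    ]
    layer = config.aligned_layer
    cost = None
    static_cost = None
    align_now = (
        round_index < config.freeze_rounds and config.variant in _VARIANT_ANCHOR
    )
    node_vectors = [
        layer_node_vectors(c.weights, layer, config.include_bias) for c in trained
    ]
    if config.record_static_cost and len(trained) > 1:
        src = WeightDistanceSource(node_vectors, config.metric)
        static_cost = matching_cost(
            identity_matching(len(trained), src.nodes_per_site), src
        )
    if align_now:
        matching = align_nodes(
            node_vectors,
            metric=config.metric,
            anchor=_VARIANT_ANCHOR[config.variant],
            seeding=config.seeding,
            rng=match_rng,
        )
        cost = matching_cost(matching, node_vectors, config.metric)
        trained = [apply_alignment(c, matching, layer) for c in trained]
        new_weights = _aggregate_aligned(trained, layer, config.force_sample_weighted)
    else:
        new_weights = fedavg_aggregate(trained)
    dispatched = [replace(c, weights=new_weights.copy()) for c in trained]
    return GlobalState(new_weights, round_index + 1), dispatched, cost, static_cost


def _spawn_seeds(base_seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(base_seed).spawn(n)]


def run_federated(
    config: FLConfig,
    fed_data: FederatedDataset,
    test_table: LabeledTable,
    init_weights: NetworkWeights | None = None,
    client_permutations: Sequence[Sequence[int]] | None = None,
) -> list[RoundRecord]:
    """Run a full federated experiment and return per-round records.

    A single shared initialization (derived from ``config.seed``, or passed
    explicitly so several variants can start identically) is dispatched to
    all clients; ``config.rounds`` federated rounds follow, with the global
    model evaluated on ``test_table`` after each.  ``client_permutations``
    optionally permutes each client's copy of the aligned hidden layer at
    start — the planted-permutation condition in which clients implement the
    same function with differently ordered neurons.

    ``variant='plain'`` instead trains one centralized model on the pooled
    client data (no aggregation), as the non-federated baseline.
    """
    if fed_data.n_clients == 0 or any(c.n_samples == 0 for c in fed_data.clients):
        raise ValueError("empty client partition")
    if config.variant != "plain" and fed_data.n_clients != config.clients:
        raise ValueError(
            f"config expects {config.clients} clients, data has {fed_data.n_clients}"
        )
    n_features = fed_data.clients[0].n_features
    arch = [n_features, *config.hidden_sizes, 1]
    seeds = _spawn_seeds(config.seed, 3)
    init_seed, match_seed, train_seed = seeds
    shared_init = init_weights if init_weights is not None else init_network(arch, init_seed)
    match_rng = np.random.default_rng(match_seed)
    train_streams = np.random.SeedSequence(train_seed).spawn(
        config.rounds * max(1, fed_data.n_clients)
    )
    records: list[RoundRecord] = []

    if config.variant == "plain":
        pooled = LabeledTable.concat(fed_data.clients)
        model = shared_init.copy()
        for t in range(config.rounds):
            rng = np.random.default_rng(train_streams[t])
            model = client_update(model, pooled.X, pooled.y, config.hyperparams, rng)
            rep = compute_metrics(test_table.y, forward(model, test_table.X))
            records.append(RoundRecord(t, "plain", None, None, rep))
        return records

    clients = []
    for k, table in enumerate(fed_data.clients):
        w = shared_init.copy()
        if client_permutations is not None:
            w = permute_hidden_units(w, config.aligned_layer, client_permutations[k])
        clients.append(ClientState(site=k, weights=w, data=table))
    state = GlobalState(shared_init.copy(), 0)
    for t in range(config.rounds):
        rngs = [
            np.random.default_rng(train_streams[t * fed_data.n_clients + k])
            for k in range(fed_data.n_clients)
        ]
        state, clients, cost, static_cost = federated_round(
            state, clients, config, t, match_rng, rngs
        )
        rep = compute_metrics(test_table.y, forward(state.weights, test_table.X))
        applied = config.variant if (t < config.freeze_rounds and
                                     config.variant in _VARIANT_ANCHOR) else "static"
        records.append(RoundRecord(t, applied, cost, static_cost, rep))
    return records


def records_to_frame(records: Sequence[RoundRecord]):
    """Round history as a pandas DataFrame (one row per round)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "round": [r.round for r in records],
            "variant": [r.variant for r in records],
            "matching_cost": np.array(
                [np.nan if r.matching_cost is None else r.matching_cost for r in records]
            ),
            "static_cost": np.array(
                [np.nan if r.static_cost is None else r.static_cost for r in records]
            ),
            "accuracy": [r.metrics.accuracy for r in records],
            "auc": [r.metrics.auc for r in records],
            "f1": [r.metrics.f1 for r in records],
            "balanced_accuracy": [r.metrics.balanced_accuracy for r in records],
            "loss": [r.metrics.loss for r in records],
        }
    )
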