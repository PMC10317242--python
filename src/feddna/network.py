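"""Minimal dense feed-forward network for binary classification.

Architecture: input -> hidden layers (ReLU) -> single sigmoid output unit,
trained with plain mini-batch SGD on binary cross-entropy.  The network is
deliberately small and written directly in numpy: the federated simulator
needs full control over weight layout (hidden-unit permutations, per-layer
aggregation) and bit-reproducible initialization, which matter more here
than raw speed.

Activations and loss are a documented convention (the local-update protocol
itself prescribes only plain SGD steps ``w <- w - eta * grad``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkWeights",
    "TrainingHyperparams",
    "init_network",
    "forward",
    "loss_and_gradients",
    "bce_loss",
    "client_update",
    "train_network",
    "train_replicates",
    "permute_hidden_units",
]


@dataclass
class TrainingHyperparams:
    """Local SGD settings: batch size ``b``, epochs ``e``, learning rate ``eta``."""

    batch_size: int = 32
    epochs: int = 2
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass(eq=False)
class NetworkWeights:
    """Ordered dense layers: ``weights[l]`` is (n_out, n_in), ``biases[l]`` is (n_out,)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must have the same layer count")
        if not self.weights:
            raise ValueError("network must have at least one layer")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.ndim != 1 or w.shape[0] != b.shape[0]:
                raise ValueError(f"layer {l} has inconsistent shapes {w.shape}, {b.shape}")
            if l > 0 and w.shape[1] != self.weights[l - 1].shape[0]:
                raise ValueError(f"layer {l} input dim does not chain from layer {l-1}")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {l} contains non-finite entries")
        if self.weights[-1].shape[0] != 1:
            raise ValueError("final layer must have exactly one output unit (binary task)")

    @property
    def architecture(self) -> list[int]:
        return [self.weights[0].shape[1]] + [w.shape[0] for w in self.weights]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights([w.copy() for w in self.weights],
                              [b.copy() for b in self.biases])

    def equals(self, other: "NetworkWeights") -> bool:
        return (
            self.architecture == other.architecture
            and all(np.array_equal(a, b) for a, b in zip(self.weights, other.weights))
            and all(np.array_equal(a, b) for a, b in zip(self.biases, other.biases))
        )

    def to_json(self, path) -> None:
        payload = {
            "architecture": self.architecture,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NetworkWeights":
        with open(path) as fh:
            payload = json.load(fh)
        net = cls(
            [np.array(w, dtype=float) for w in payload["weights"]],
            [np.array(b, dtype=float) for b in payload["biases"]],
        )
        if net.architecture != payload["architecture"]:
            raise ValueError("architecture header does not match stored arrays")
        return net


def init_network(architecture: Sequence[int], seed) -> NetworkWeights:
    """Glorot-style uniform initialization, fully determined by ``seed``.

    ``architecture`` lists layer sizes input-first, e.g. ``[10, 10, 8, 1]``.
    Identical seeds give bit-identical weights, which is what lets every
    federated method start from the same shared initialization.
    """
    arch = [int(s) for s in architecture]
    if len(arch) < 2:
        raise ValueError("architecture needs at least input and output sizes")
    if any(s <= 0 for s in arch):
        raise ValueError("layer sizes must be positive")
    if arch[-1] != 1:
        raise ValueError("output layer must have size 1 (binary task)")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(arch[:-1], arch[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return NetworkWeights(weights, biases)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_pass(net: NetworkWeights, X: np.ndarray):
    """Return (pre-activations per layer, activations per layer incl. input)."""
    acts = [X]
    zs = []
    a = X
    for l in range(net.n_layers):
        z = a @ net.weights[l].T + net.biases[l]
        zs.append(z)
        a = np.maximum(z, 0.0) if l < net.n_layers - 1 else _sigmoid(z)
        acts.append(a)
    return zs, acts


def _check_features(net: NetworkWeights, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != net.architecture[0]:
        raise ValueError(
            f"feature matrix shape {X.shape} incompatible with input size "
            f"{net.architecture[0]}"
        )
    return X


def forward(net: NetworkWeights, X) -> np.ndarray:
    """Predicted positive-class probability per sample, shape (n_samples,)."""
    X = _check_features(net, X)
    _, acts = _forward_pass(net, X)
    return acts[-1][:, 0]


def bce_loss(labels, probabilities, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of probabilities against 0/1 labels."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probabilities, dtype=float), eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def loss_and_gradients(net: NetworkWeights, X, y):
    """Mean BCE loss and its analytic gradients for one batch.

    The loss is computed from the output logits (softplus form) for numerical
    stability; gradients come from standard backpropagation with the ReLU
    subgradient at 0 taken as 0.
    """
    X = _check_features(net, X)
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must be one per sample")
    zs, acts = _forward_pass(net, X)
    n = X.shape[0]
    z_out = zs[-1][:, 0]
    # softplus(z) - y z = -[y log p + (1-y) log(1-p)] for p = sigmoid(z)
    loss = float(np.mean(np.logaddexp(0.0, z_out) - y * z_out))
    delta = ((acts[-1][:, 0] - y) / n)[:, None]  # dL/dz_out
    grads_w = [np.empty_like(w) for w in net.weights]
    grads_b = [np.empty_like(b) for b in net.biases]
    for l in range(net.n_layers - 1, -1, -1):
        grads_w[l] = delta.T @ acts[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ net.weights[l]) * (zs[l - 1] > 0)
    return loss, grads_w, grads_b


def _check_binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty data")
    vals = np.unique(y)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError(f"labels must be binary 0/1, got values {vals}")
    return y.astype(float)


def client_update(net: NetworkWeights, X, y, hp: TrainingHyperparams, rng) -> NetworkWeights:
    """``e`` epochs of mini-batch SGD on local data; returns new weights.

    Batches are drawn in a fresh random order (from ``rng``) each epoch; the
    final partial batch is kept.  The input network is not mutated.
    """
    X = _check_features(net, X)
    y = _check_binary_labels(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("feature/label row counts differ")
    rng = np.random.default_rng(rng)
    out = net.copy()
    n = X.shape[0]
    eta = hp.learning_rate
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            _, gw, gb = loss_and_gradients(out, X[idx], y[idx])
            for l in range(out.n_layers):
                out.weights[l] -= eta * gw[l]
                out.biases[l] -= eta * gb[l]
    return out


def train_network(
    net: NetworkWeights,
    X,
    y,
    hp: TrainingHyperparams | None = None,
    rng=None,
    max_epochs: int = 200,
    tol: float = 1e-4,
    patience: int = 3,
) -> NetworkWeights:
    """Train until the epoch loss stops improving (or ``max_epochs``).

    Convergence rule: stop once the full-data loss has improved by less than
    ``tol`` for ``patience`` consecutive epochs.
    """
    hp = hp or TrainingHyperparams()
    rng = np.random.default_rng(rng)
    one_epoch = replace(hp, epochs=1)
    out = net
    best = bce_loss(y, forward(out, X))
    stall = 0
    for _ in range(max_epochs):
        out = client_update(out, X, y, one_epoch, rng)
        loss = bce_loss(y, forward(out, X))
        if best - loss < tol:
            stall += 1
            if stall >= patience:
                break
        else:
            stall = 0
        best = min(best, loss)
    return out


def train_replicates(
    architecture: Sequence[int],
    X,
    y,
    count: int,
    base_seed: int,
    hp: TrainingHyperparams | None = None,
    max_epochs: int = 200,
    seeds: Sequence[int] | None = None,
) -> list[NetworkWeights]:
    """Train ``count`` networks from scratch on the *same* data.

    Each replicate gets a distinct initialization/shuffling seed derived from
    ``base_seed`` (override via ``seeds`` — e.g. identical seeds reproduce
    identical networks).  Used by the node-weight-variance diagnostic, which
    asks how stable individual hidden units are across retrainings.
    """
    if count < 2:
        raise ValueError("need at least 2 replicates")
    if seeds is None:
        seed_list = [s.generate_state(1)[0] % (2**31)
                     for s in np.random.SeedSequence(base_seed).spawn(count)]
    else:
        if len(seeds) != count:
            raise ValueError("seeds must have one entry per replicate")
        seed_list = [int(s) for s in seeds]
    nets = []
    for s in seed_list:
        net = init_network(architecture, s)
        nets.append(train_network(net, X, y, hp=hp, rng=s, max_epochs=max_epochs))
    return nets


def layer_node_vectors(net: NetworkWeights, layer: int, include_bias: bool = False) -> np.ndarray:
    """Per-node incoming-weight vectors of one layer, as an (n, m) array.

    With ``include_bias`` the unit's bias is appended as dimension m+1, so
    alignment can optionally compare the full affine map of each unit;
    default is weights only.
    """
    W = net.weights[layer]
    if include_bias:
        return np.hstack([W, net.biases[layer][:, None]])
    return W


def permute_hidden_units(net: NetworkWeights, layer: int, perm: Sequence[int]) -> NetworkWeights:
    """Reorder hidden layer ``layer``'s units by ``perm`` (function-preserving).

    ``perm[j]`` gives the old unit placed at new index ``j``.  Rows of the
    layer's weight matrix and its biases are permuted together with the
    matching input columns of the next layer, so the network's input–output
    map is unchanged.
    """
    if not (0 <= layer < net.n_layers - 1):
        raise ValueError(f"layer {layer} is not a hidden layer of this network")
    perm = np.asarray(perm, dtype=int)
    n = net.weights[layer].shape[0]
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError(f"perm must be a permutation of 0..{n-1}")
    out = net.copy()
    out.weights[layer] = out.weights[layer][perm]
    out.biases[layer] = out.biases[layer][perm]
    out.weights[layer + 1] = out.weights[layer + 1][:, perm]
    return out
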