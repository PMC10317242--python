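"""Synthetic tabular data, CSV ingestion, and federated client partitioning.

The synthetic generator emulates small clinical-style binary-classification
benchmarks (diabetes screening, room occupancy, ICU survival, spam): a
two-class Gaussian mixture over ``n_features`` columns in which an
``informative_fraction`` of features carry a class-mean gap of
``class_separation * noise_sd`` and the rest are pure noise, with an exact
negative:positive label ratio.  Client heterogeneity is produced by
class-ratio downsampling, random or stratified partitioning into K sites,
and a two-client data exchange that swaps a fraction of two sites' samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "LabeledTable",
    "SyntheticSpec",
    "FederatedDataset",
    "generate_synthetic",
    "load_csv",
    "save_csv",
    "resample_ratio",
    "partition_clients",
    "exchange_two_clients",
    "minmax_scale",
    "train_test_split_table",
]


@dataclass
class LabeledTable:
    """A feature matrix with binary labels and feature names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("one label per row required")
        if not np.all(np.isin(np.unique(self.y), [0, 1])):
            raise ValueError("labels must be binary 0/1")
        self.y = self.y.astype(int)
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one name per feature column required")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        pos = int(self.y.sum())
        return self.n_samples - pos, pos

    @property
    def neg_pos_ratio(self) -> float:
        neg, pos = self.class_counts
        return neg / pos if pos else float("inf")

    def subset(self, idx) -> "LabeledTable":
        idx = np.asarray(idx)
        return LabeledTable(self.X[idx], self.y[idx], list(self.feature_names))

    @staticmethod
    def concat(tables: list["LabeledTable"]) -> "LabeledTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        names = tables[0].feature_names
        return LabeledTable(
            np.vstack([t.X for t in tables]),
            np.concatenate([t.y for t in tables]),
            list(names),
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        return df


@dataclass
class SyntheticSpec:
    """Parameters of the two-class Gaussian-mixture generator.

    ``neg_pos_ratio`` follows the benchmark convention negative:positive
    (e.g. 1.54 means ~60% negatives); ``class_separation`` is the class-mean
    gap of informative features in units of ``noise_sd``.
    """

    n_samples: int = 1000
    n_features: int = 10
    neg_pos_ratio: float = 1.0
    class_separation: float = 2.0
    noise_sd: float = 1.0
    informative_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_features < 1:
            raise ValueError("need at least 1 feature")
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg_pos_ratio must be > 0")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 < self.informative_fraction <= 1):
            raise ValueError("informative_fraction must be in (0, 1]")


def generate_synthetic(spec: SyntheticSpec, seed) -> LabeledTable:
    """Draw a labeled table from ``spec``, fully reproducible by ``seed``.

    Label counts realize ``neg_pos_ratio`` exactly after rounding: with
    ratio r, positives = round(n / (1 + r)).  Informative features of class 0
    are centered at -gap/2 and of class 1 at +gap/2 with gap =
    ``class_separation * noise_sd``; remaining features are N(0, noise_sd)
    for both classes.  Rows are shuffled so classes are interleaved.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    n_pos = int(round(n / (1.0 + spec.neg_pos_ratio)))
    n_neg = n - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            f"ratio {spec.neg_pos_ratio} infeasible for n_samples={n}: "
            f"would give {n_neg} negatives / {n_pos} positives"
        )
    m = spec.n_features
    n_inf = max(1, int(round(spec.informative_fraction * m)))
    gap = spec.class_separation * spec.noise_sd
    X = rng.normal(0.0, spec.noise_sd, size=(n, m))
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    X[: n_neg, :n_inf] -= gap / 2.0
    X[n_neg:, :n_inf] += gap / 2.0
    order = rng.permutation(n)
    return LabeledTable(X[order], y[order])


def load_csv(path, label_column: str) -> LabeledTable:
    """Read a labeled table from CSV.

    The label column may hold any two distinct values (mapped to 0/1 in
    sorted order, with {0,1} kept as-is).  Non-numeric feature columns are
    one-hot encoded; the resulting column order is deterministic (original
    order, indicator columns expanding in level order).
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    raw = df[label_column]
    levels = sorted(raw.dropna().unique().tolist(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"label column must hold exactly 2 distinct values, got {levels}"
        )
    if set(levels) == {0, 1}:
        y = raw.astype(int).to_numpy()
    else:
        y = (raw == levels[1]).astype(int).to_numpy()
    feats = df.drop(columns=[label_column])
    non_numeric = [c for c in feats.columns if not pd.api.types.is_numeric_dtype(feats[c])]
    if non_numeric:
        feats = pd.get_dummies(feats, columns=non_numeric, dtype=float)
    feats = feats.astype(float)
    return LabeledTable(feats.to_numpy(), y, [str(c) for c in feats.columns])


def save_csv(table: LabeledTable, path, label_column: str = "label") -> None:
    table.to_frame(label_column).to_csv(path, index=False)


def resample_ratio(table: LabeledTable, target_ratio: float, seed) -> LabeledTable:
    """Downsample one class so negative:positive matches ``target_ratio``.

    Only downsampling is performed (no synthetic augmentation): if the table
    is too negative-heavy, negatives are subsampled, otherwise positives.
    The realized ratio is within one sample of the target.  Idempotent at an
    already-achieved ratio.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be > 0")
    neg_idx = np.flatnonzero(table.y == 0)
    pos_idx = np.flatnonzero(table.y == 1)
    if len(neg_idx) == 0 or len(pos_idx) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    if len(neg_idx) / len(pos_idx) >= target_ratio:
        want_neg = int(round(target_ratio * len(pos_idx)))
        if want_neg < 1:
            raise ValueError(
                f"target ratio {target_ratio} unreachable: negative class would "
                f"be emptied (positives limit the ratio)"
            )
        if want_neg < len(neg_idx):
            neg_idx = rng.choice(neg_idx, size=want_neg, replace=False)
    else:
        want_pos = int(round(len(neg_idx) / target_ratio))
        if want_pos < 1:
            raise ValueError(
                f"target ratio {target_ratio} unreachable: positive class would "
                f"be emptied (negatives limit the ratio)"
            )
        if want_pos < len(pos_idx):
            pos_idx = rng.choice(pos_idx, size=want_pos, replace=False)
    keep = np.sort(np.concatenate([neg_idx, pos_idx]))
    return table.subset(keep)


@dataclass
class FederatedDataset:
    """Per-client disjoint shards of one training table."""

    clients: list[LabeledTable]
    provenance: str = "iid"
    client_indices: list[np.ndarray] | None = None  # rows into the source table

    @property
    def n_clients(self) -> int:
        return len(self.clients)

    @property
    def sample_counts(self) -> list[int]:
        return [c.n_samples for c in self.clients]

    def manifest(self) -> dict:
        """Audit manifest: provenance plus per-client source row indices."""
        return {
            "provenance": self.provenance,
            "n_clients": self.n_clients,
            "sample_counts": self.sample_counts,
            "client_indices": None
            if self.client_indices is None
            else [idx.tolist() for idx in self.client_indices],
        }


def partition_clients(
    table: LabeledTable, n_clients: int, stratified: bool = False, seed=None
) -> FederatedDataset:
    """Split a table into ``n_clients`` disjoint near-equal shards.

    Stratified mode distributes each class round-robin so every shard keeps
    the source class ratio up to rounding.
    """
    if n_clients < 1:
        raise ValueError("need at least one client")
    if table.n_samples < n_clients:
        raise ValueError(
            f"cannot split {table.n_samples} samples across {n_clients} clients"
        )
    rng = np.random.default_rng(seed)
    if stratified:
        shards: list[list[int]] = [[] for _ in range(n_clients)]
        for cls in (0, 1):
            idx = rng.permutation(np.flatnonzero(table.y == cls))
            for pos, i in enumerate(idx):
                shards[pos % n_clients].append(int(i))
        parts = [np.sort(np.array(s, dtype=int)) for s in shards]
    else:
        order = rng.permutation(table.n_samples)
        parts = [np.sort(chunk) for chunk in np.array_split(order, n_clients)]
    return FederatedDataset(
        [table.subset(p) for p in parts], provenance="iid", client_indices=parts
    )


def exchange_two_clients(fed: FederatedDataset, fraction: float = 2.0 / 3.0, rng=None) -> FederatedDataset:
    """Swap a random ``fraction`` of samples between two random clients.

    Two distinct clients are drawn; each sends a uniformly chosen
    ``floor(fraction * n_k)`` subset of its rows to the other (a swap, so
    every client keeps its sample count and the overall multiset of samples
    is conserved).  The remaining clients are untouched.  This induces the
    non-IID condition in which two sites' local distributions are largely
    each other's.
    """
    if fed.n_clients < 2:
        raise ValueError("need at least two clients to exchange")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(rng)
    a, b = rng.choice(fed.n_clients, size=2, replace=False)
    a, b = int(a), int(b)
    ta, tb = fed.clients[a], fed.clients[b]
    ka = int(np.floor(fraction * ta.n_samples))
    kb = int(np.floor(fraction * tb.n_samples))
    send_a = rng.choice(ta.n_samples, size=ka, replace=False)
    send_b = rng.choice(tb.n_samples, size=kb, replace=False)
    keep_a = np.setdiff1d(np.arange(ta.n_samples), send_a)
    keep_b = np.setdiff1d(np.arange(tb.n_samples), send_b)
    new_a = LabeledTable.concat([ta.subset(keep_a), tb.subset(send_b)])
    new_b = LabeledTable.concat([tb.subset(keep_b), ta.subset(send_a)])
    clients = list(fed.clients)
    clients[a], clients[b] = new_a, new_b
    indices = None
    if fed.client_indices is not None:
        indices = [idx.copy() for idx in fed.client_indices]
        ia, ib = indices[a], indices[b]
        indices[a] = np.concatenate([ia[keep_a], ib[send_b]])
        indices[b] = np.concatenate([ib[keep_b], ia[send_a]])
    return FederatedDataset(clients, provenance="exchanged", client_indices=indices)


def minmax_scale(train: LabeledTable, *others: LabeledTable):
    """Min-max scale to [0,1], with the scaler fitted on ``train`` only.

    Returns the scaled train table followed by the scaled ``others`` (test
    splits, client shards, ...), so no statistics leak from evaluation data.
    """
    scaler = MinMaxScaler().fit(train.X)
    out = [LabeledTable(scaler.transform(train.X), train.y, list(train.feature_names))]
    for t in others:
        out.append(LabeledTable(scaler.transform(t.X), t.y, list(t.feature_names)))
    return out[0] if not others else tuple(out)


def train_test_split_table(table: LabeledTable, test_fraction: float, seed):
    """Stratified train/test split of a labeled table."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(table.y == cls))
        k = int(round(test_fraction * len(idx)))
        test_idx.extend(idx[:k].tolist())
    test_mask = np.zeros(table.n_samples, dtype=bool)
    test_mask[test_idx] = True
    return table.subset(np.flatnonzero(~test_mask)), table.subset(np.flatnonzero(test_mask))
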