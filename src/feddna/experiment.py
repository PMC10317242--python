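"""Cross-validated experiment harness and reference benchmarks.

``crossval_experiment`` runs the full protocol: stratified K-fold splits,
min-max scaling fitted on each training fold, random partitioning of the
training fold into client shards, and every requested method started from
the same shared initialization within a fold.

``run_alignment_benchmark`` builds the planted-permutation non-IID study
condition used to compare dynamic alignment against static averaging: a
synthetic two-class task, five clients of which two exchange two thirds of
their data, and per-client random permutations of the shared initial hidden
layer (each client implements the same initial function with differently
ordered neurons — the ambiguity index-wise averaging cannot see).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import (
    FederatedDataset,
    LabeledTable,
    SyntheticSpec,
    exchange_two_clients,
    generate_synthetic,
    minmax_scale,
    partition_clients,
    train_test_split_table,
)
from .federation import FLConfig, RoundRecord, records_to_frame, run_federated

__all__ = [
    "ExperimentResult",
    "crossval_experiment",
    "run_alignment_benchmark",
    "BENCHMARK_SPEC",
]

DEFAULT_METHODS = ("plain", "static", "dynamic", "fixed", "random")


@dataclass
class ExperimentResult:
    """Per-fold, per-method round histories plus summary statistics."""

    histories: dict[tuple[int, str], list[RoundRecord]]
    n_folds: int
    methods: tuple[str, ...]

    def final_metrics_frame(self) -> pd.DataFrame:
        rows = []
        for (fold, method), records in self.histories.items():
            last = records[-1]
            mean_cost = np.mean(
                [r.matching_cost for r in records if r.matching_cost is not None]
            ) if any(r.matching_cost is not None for r in records) else np.nan
            rows.append(
                {
                    "fold": fold,
                    "method": method,
                    "distance": mean_cost,
                    "accuracy": last.metrics.accuracy,
                    "auc": last.metrics.auc,
                    "f1": last.metrics.f1,
                    "balanced_accuracy": last.metrics.balanced_accuracy,
                    "loss": last.metrics.loss,
                }
            )
        return pd.DataFrame(rows).sort_values(["fold", "method"]).reset_index(drop=True)

    def summary(self) -> pd.DataFrame:
        """Mean of final-round metrics per method across folds."""
        df = self.final_metrics_frame()
        return df.groupby("method", sort=True).mean(numeric_only=True).drop(columns="fold")


def crossval_experiment(
    config: FLConfig,
    table: LabeledTable,
    methods: Sequence[str] = DEFAULT_METHODS,
    n_folds: int = 10,
) -> ExperimentResult:
    """Stratified K-fold comparison of federated methods on one table.

    Within each fold every method runs from the same seed (hence the same
    shared initialization); evaluation is on the held-out fold.  Scaling is
    fitted on the training fold only.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    neg, pos = table.class_counts
    if min(neg, pos) < n_folds:
        raise ValueError("too few samples of the minority class for the fold count")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed % (2**31))
    histories: dict[tuple[int, str], list[RoundRecord]] = {}
    for fold, (train_idx, test_idx) in enumerate(splitter.split(table.X, table.y)):
        train_raw = table.subset(train_idx)
        test_raw = table.subset(test_idx)
        train, test = minmax_scale(train_raw, test_raw)
        fed = partition_clients(train, config.clients, stratified=False,
                                seed=(config.seed + 7919 * (fold + 1)) % (2**31))
        for method in methods:
            cfg = replace(config, variant=method)
            histories[(fold, method)] = run_federated(cfg, fed, test)
    return ExperimentResult(histories, n_folds, tuple(methods))


#: synthetic study condition for the scaled-down alignment benchmark
BENCHMARK_SPEC = SyntheticSpec(
    n_samples=1400,
    n_features=10,
    neg_pos_ratio=1.0,
    class_separation=2.0,
    noise_sd=1.0,
    informative_fraction=0.5,
)


def run_alignment_benchmark(
    seed: int,
    variants: Sequence[str] = ("dynamic", "static"),
    config: FLConfig | None = None,
    spec: SyntheticSpec = BENCHMARK_SPEC,
) -> Mapping[str, list[RoundRecord]]:
    """One seed of the planted-permutation non-IID benchmark.

    Generates the synthetic task, splits ~30% off as the test set, scales,
    partitions the rest across the configured clients, lets two random
    clients exchange 2/3 of their data (non-IID condition), draws one random
    hidden-unit permutation per client for the shared initialization, and
    runs each requested variant from identical state.  Returns the round
    histories keyed by variant.
    """
    cfg = config or FLConfig(seed=int(seed))
    cfg = replace(cfg, seed=int(seed))
    rng = np.random.default_rng(int(seed))
    table = generate_synthetic(spec, rng.integers(2**31))
    train_raw, test_raw = train_test_split_table(table, 2.0 / 7.0, rng.integers(2**31))
    train, test = minmax_scale(train_raw, test_raw)
    fed = partition_clients(train, cfg.clients, seed=rng.integers(2**31))
    fed = exchange_two_clients(fed, 2.0 / 3.0, rng)
    width = cfg.hidden_sizes[cfg.aligned_layer]
    perms = [rng.permutation(width) for _ in range(cfg.clients)]
    out: dict[str, list[RoundRecord]] = {}
    for variant in variants:
        vcfg = replace(cfg, variant=variant)
        out[variant] = run_federated(vcfg, fed, test, client_permutations=perms)
    return out


def benchmark_summary(histories: Mapping[str, Sequence[RoundRecord]]) -> pd.DataFrame:
    """Flatten per-variant benchmark histories into one DataFrame."""
    frames = []
    for variant, records in histories.items():
        df = records_to_frame(records)
        df.insert(0, "method", variant)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
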