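"""Evaluation metrics and the node-weight-variance diagnostic.

``compute_metrics`` wraps the standard binary-classification measures
(accuracy, ROC AUC, F1, balanced accuracy, mean binary cross-entropy).

``node_weight_variance`` quantifies how unstable individual hidden units are
across retrainings of the same network on the same data: under the *static*
grouping, the variance of each weight w[i, d] is taken across replicates at
a fixed node index i — which mixes unrelated neurons whenever replicates
converge to permuted solutions.  Under the *dynamic* grouping, replicates
are first aligned (each replicate treated as a site in the tree-matching
procedure) and variances are taken within matched groups instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    log_loss,
    roc_auc_score,
)

from .matching import MatchingResult, align_nodes, identity_matching
from .network import NetworkWeights

__all__ = ["MetricsReport", "VarianceReport", "compute_metrics", "node_weight_variance"]


@dataclass
class MetricsReport:
    """Standard binary-classification measures on one evaluation split.

    ``auc`` is NaN when only one class is present in the labels (the rank
    statistic is undefined); all other fields are always computed.
    """

    accuracy: float
    auc: float
    f1: float
    balanced_accuracy: float
    loss: float

    @property
    def auc_defined(self) -> bool:
        return not math.isnan(self.auc)


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Score probability predictions against binary labels.

    Accuracy, F1 (positive class) and balanced accuracy (mean of sensitivity
    and specificity) are taken at ``threshold``; AUC is the rank statistic on
    the raw scores; loss is mean binary cross-entropy.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equal length")
    if not np.all(np.isin(np.unique(y), [0, 1])):
        raise ValueError("labels must be binary 0/1")
    if np.any((s < 0) | (s > 1)) or not np.all(np.isfinite(s)):
        raise ValueError("scores must lie in [0, 1]")
    y = y.astype(int)
    pred = (s >= threshold).astype(int)
    if len(np.unique(y)) < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, s))
    return MetricsReport(
        accuracy=float(accuracy_score(y, pred)),
        auc=auc,
        f1=float(f1_score(y, pred, zero_division=0)),
        balanced_accuracy=float(balanced_accuracy_score(y, pred)),
        loss=float(log_loss(y, np.clip(s, 1e-12, 1 - 1e-12), labels=[0, 1])),
    )


@dataclass
class VarianceReport:
    """Across-replicate weight variances for one hidden layer.

    ``per_node`` is (n_nodes, n_dims): sample variance of each weight across
    replicates within its group; ``per_node_mean`` averages over dimensions.
    ``grouping`` names the node grouping used; ``matching`` carries the
    alignment when the grouping is dynamic.
    """

    per_node: np.ndarray
    per_node_mean: np.ndarray
    grouping: str
    matching: MatchingResult | None = None

    @property
    def mean_variance(self) -> float:
        return float(self.per_node_mean.mean())


def node_weight_variance(
    replicates: Sequence[NetworkWeights],
    layer: int = 0,
    grouping="static",
    metric: str = "manhattan",
    seeding: str = "random",
    rng=None,
) -> VarianceReport:
    """Per-node weight variance across replicate networks.

    ``grouping`` is ``'static'`` (fixed node indices), ``'dynamic'`` (align
    the replicates first, treating each as a site), or an explicit
    :class:`MatchingResult` over the replicates.  Variances use ddof=1.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    arch = replicates[0].architecture
    for r in replicates[1:]:
        if r.architecture != arch:
            raise ValueError("replicate architectures differ")
    mats = [r.weights[layer] for r in replicates]
    n, _ = mats[0].shape
    if isinstance(grouping, MatchingResult):
        matching = grouping
        name = "custom"
    elif grouping == "static":
        matching = identity_matching(len(replicates), n)
        name = "static"
    elif grouping == "dynamic":
        matching = align_nodes(
            mats, metric=metric, seeding=seeding,
            rng=np.random.default_rng(rng if rng is not None else 0),
        )
        name = "dynamic"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    grouped = np.empty((len(matching.trees), len(replicates), mats[0].shape[1]))
    for j, tree in enumerate(matching.trees):
        for r, member in enumerate(sorted(tree.members)):  # site == replicate index
            grouped[j, r] = mats[member.site][member.node]
    per_node = grouped.var(axis=1, ddof=1)
    return VarianceReport(
        per_node=per_node,
        per_node_mean=per_node.mean(axis=1),
        grouping=name,
        matching=None if name == "static" else matching,
    )
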