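"""Cross-site neuron alignment by greedy minimum-spanning-tree matching.

Dense networks are permutation-invariant in their hidden units: two networks
trained on the same task can implement the same function with hidden neurons
in different orders.  Index-wise ("static") weight averaging across federated
sites therefore mixes unrelated neurons.  This module aligns neurons across
sites by the similarity of their incoming-weight vectors: a matching *tree*
is grown greedily, one neuron per site, always joining the candidate neuron
whose distance to the tree (minimum distance to any current member) is
smallest.  Repeating until every neuron belongs to exactly one complete tree
yields a partition of all ``sites x nodes`` neurons into matched groups whose
weights can then be averaged.

The module also provides two anchor variants used as baselines (matching
against the tree's seed only, or against one uniformly drawn member), an
exhaustive optimal-matching oracle for small instances, and the scalar
matching-cost statistic (sum of tree join distances).
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NodeRef",
    "MatchTree",
    "MatchingResult",
    "DistanceTable",
    "DistanceSource",
    "WeightDistanceSource",
    "TableDistanceSource",
    "MatchingConstraintError",
    "SizeLimitError",
    "METRICS",
    "ANCHOR_MODES",
    "SEEDING_MODES",
    "node_distance",
    "build_distance_table",
    "tree_distance",
    "grow_tree",
    "align_nodes",
    "identity_matching",
    "matching_cost",
    "optimal_matching",
]

METRICS = ("euclidean", "manhattan")
ANCHOR_MODES = ("all_members", "seed_only", "random_member")
SEEDING_MODES = ("random", "global_min")


class MatchingConstraintError(ValueError):
    """A matching rule was violated (e.g. two nodes of one site in a tree)."""


class SizeLimitError(ValueError):
    """Instance exceeds the guard of the exhaustive optimal-matching oracle."""


@dataclass(frozen=True, order=True)
class NodeRef:
    """Reference to one neuron: ``site`` (client index) and ``node`` index.

    Both indices are 0-based.  Ordering is lexicographic on (site, node),
    which is the deterministic tie-break used throughout the matching code.
    """

    site: int
    node: int


def _check_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def _check_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return metric


def node_distance(u, v, metric: str = "euclidean") -> float:
    """Distance between two neurons' incoming-weight vectors.

    ``euclidean`` is the length of the line segment between the two points
    (square root of the sum of squared coordinate differences); ``manhattan``
    is the sum of absolute coordinate differences.

    Raises
    ------
    ValueError
        If the vectors differ in length, contain non-finite entries, or the
        metric name is unknown.
    """
    _check_metric(metric)
    a = _check_vector(u, "u")
    b = _check_vector(v, "v")
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    if metric == "euclidean":
        return float(np.sqrt(np.dot(diff, diff)))
    return float(np.sum(np.abs(diff)))


# ---------------------------------------------------------------------------
# Distance sources
# ---------------------------------------------------------------------------


class DistanceSource:
    """Abstract provider of cross-site node distances.

    Matching operations are written against this interface so they can run
    either on raw weight vectors (:class:`WeightDistanceSource`) or on
    precomputed distance tables (:class:`TableDistanceSource`), e.g. the
    printed three-site worked example.
    """

    n_sites: int
    nodes_per_site: int

    def distance(self, a: NodeRef, b: NodeRef) -> float:
        raise NotImplementedError

    def _check_refs(self, a: NodeRef, b: NodeRef) -> None:
        for r in (a, b):
            if not (0 <= r.site < self.n_sites and 0 <= r.node < self.nodes_per_site):
                raise ValueError(f"node reference {r} out of range")
        if a.site == b.site:
            raise MatchingConstraintError(
                f"distance requested between two nodes of the same site {a.site}"
            )

    def all_refs(self) -> list[NodeRef]:
        return [
            NodeRef(s, i)
            for s in range(self.n_sites)
            for i in range(self.nodes_per_site)
        ]


class WeightDistanceSource(DistanceSource):
    """Distances computed on demand from per-site weight matrices.

    Pairwise results are memoized, so each unordered cross-site pair is
    evaluated at most once; ``n_evaluations`` counts the actual vector
    computations (the quantity bounded by the complexity analysis).
    """

    def __init__(self, layer_weights: Sequence[np.ndarray], metric: str = "euclidean"):
        _check_metric(metric)
        if len(layer_weights) < 2:
            raise ValueError("need at least two sites")
        mats = [np.asarray(w, dtype=float) for w in layer_weights]
        shape = mats[0].shape
        if len(shape) != 2:
            raise ValueError("each site's layer weights must be a 2-D (nodes x dims) array")
        for i, m in enumerate(mats):
            if m.shape != shape:
                raise ValueError(
                    f"site {i} layer shape {m.shape} differs from site 0 shape {shape}"
                )
            if not np.all(np.isfinite(m)):
                raise ValueError(f"site {i} layer contains non-finite entries")
        self._mats = mats
        self.metric = metric
        self.n_sites = len(mats)
        self.nodes_per_site = shape[0]
        self.n_dims = shape[1]
        self.n_evaluations = 0
        self._cache: dict[tuple[NodeRef, NodeRef], float] = {}

    def distance(self, a: NodeRef, b: NodeRef) -> float:
        self._check_refs(a, b)
        key = (a, b) if a <= b else (b, a)
        d = self._cache.get(key)
        if d is None:
            d = node_distance(
                self._mats[a.site][a.node], self._mats[b.site][b.node], self.metric
            )
            self._cache[key] = d
            self.n_evaluations += 1
        return d

    def vector(self, ref: NodeRef) -> np.ndarray:
        return self._mats[ref.site][ref.node]


class TableDistanceSource(DistanceSource):
    """Distances looked up from precomputed site-pair tables.

    ``tables`` maps an ordered site pair ``(i, j)`` to an ``n x n`` matrix
    whose ``(p, q)`` entry is the distance between node ``p`` of site ``i``
    and node ``q`` of site ``j``.  Every cross-site pair must be covered in
    one orientation; symmetry is implied.
    """

    def __init__(self, tables: Mapping[tuple[int, int], np.ndarray], n_sites: int):
        if n_sites < 2:
            raise ValueError("need at least two sites")
        norm: dict[tuple[int, int], np.ndarray] = {}
        n_nodes = None
        for (i, j), mat in tables.items():
            arr = np.asarray(mat, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                raise ValueError(f"table for sites ({i},{j}) must be square")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"table for sites ({i},{j}) must be finite and >= 0")
            if n_nodes is None:
                n_nodes = arr.shape[0]
            elif arr.shape[0] != n_nodes:
                raise ValueError("all tables must share the same node count")
            if i == j:
                raise MatchingConstraintError("same-site distance table not allowed")
            norm[(i, j)] = arr
        if n_nodes is None:
            raise ValueError("no tables provided")
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                if (i, j) not in norm and (j, i) not in norm:
                    raise ValueError(f"missing distance table for site pair ({i},{j})")
        self._tables = norm
        self.n_sites = n_sites
        self.nodes_per_site = int(n_nodes)
        self.n_evaluations = 0  # lookups, kept for interface parity

    def distance(self, a: NodeRef, b: NodeRef) -> float:
        self._check_refs(a, b)
        self.n_evaluations += 1
        if (a.site, b.site) in self._tables:
            return float(self._tables[(a.site, b.site)][a.node, b.node])
        return float(self._tables[(b.site, a.site)][b.node, a.node])


def _as_source(layer_weights, metric: str) -> DistanceSource:
    if isinstance(layer_weights, DistanceSource):
        return layer_weights
    return WeightDistanceSource(layer_weights, metric)


# ---------------------------------------------------------------------------
# Distance tables
# ---------------------------------------------------------------------------


@dataclass
class DistanceTable:
    """A labeled block of pairwise node distances between two sites."""

    row_site: int
    col_site: int
    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label counts do not match value shape")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distance entries must be finite and >= 0")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([f"site{self.row_site}|site{self.col_site}", *self.col_labels])
            for label, row in zip(self.row_labels, self.values):
                writer.writerow([label, *[repr(float(x)) for x in row]])

    @classmethod
    def from_csv(cls, path) -> "DistanceTable":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise ValueError(f"empty distance-table file {path}")
        header = rows[0]
        try:
            row_site_s, col_site_s = header[0].split("|")
            row_site = int(row_site_s.removeprefix("site"))
            col_site = int(col_site_s.removeprefix("site"))
        except (ValueError, IndexError) as exc:
            raise ValueError(
                "first header cell must look like 'site<i>|site<j>'"
            ) from exc
        col_labels = header[1:]
        row_labels = [r[0] for r in rows[1:]]
        values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(row_site, col_site, row_labels, col_labels, values)


def build_distance_table(
    nodes_a: Sequence, nodes_b: Sequence, metric: str = "euclidean",
    row_site: int = 0, col_site: int = 1,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> DistanceTable:
    """Materialize the pairwise distance block between two node lists."""
    if len(nodes_a) == 0 or len(nodes_b) == 0:
        raise ValueError("node lists must be nonempty")
    values = np.array(
        [[node_distance(u, v, metric) for v in nodes_b] for u in nodes_a]
    )
    if row_labels is None:
        row_labels = [str(i) for i in range(len(nodes_a))]
    if col_labels is None:
        col_labels = [str(j) for j in range(len(nodes_b))]
    return DistanceTable(row_site, col_site, list(row_labels), list(col_labels), values)


def tables_to_source(tables: Iterable[DistanceTable], n_sites: int) -> TableDistanceSource:
    """Assemble per-site-pair :class:`DistanceTable` blocks into a source."""
    mapping = {(t.row_site, t.col_site): t.values for t in tables}
    return TableDistanceSource(mapping, n_sites)


# ---------------------------------------------------------------------------
# Trees and matchings
# ---------------------------------------------------------------------------


@dataclass
class MatchTree:
    """A growing group of matched neurons, at most one per site.

    ``members`` is in join order; the first member is the seed.
    ``join_distances`` records the node-to-tree distance at which each member
    after the seed joined; it is ``None`` for groupings assembled without a
    recorded growth (identity / oracle groupings), in which case
    :func:`matching_cost` replays the joins.
    """

    members: list[NodeRef]
    join_distances: list[float] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for m in self.members:
            if m.site in seen:
                raise MatchingConstraintError(
                    f"tree holds two nodes of site {m.site}"
                )
            seen.add(m.site)
        if self.join_distances is not None:
            if len(self.join_distances) != len(self.members) - 1:
                raise ValueError("join_distances must have one entry per non-seed member")
            if any(d < 0 for d in self.join_distances):
                raise ValueError("join distances must be >= 0")

    @property
    def seed(self) -> NodeRef:
        return self.members[0]

    @property
    def sites(self) -> set[int]:
        return {m.site for m in self.members}

    def member_for_site(self, site: int) -> NodeRef:
        for m in self.members:
            if m.site == site:
                return m
        raise KeyError(f"site {site} not in tree")


@dataclass
class MatchingResult:
    """A partition of all (site, node) pairs of one layer into complete trees."""

    trees: list[MatchTree]
    sites: int
    nodes_per_site: int

    def __post_init__(self) -> None:
        expected = {
            NodeRef(s, i)
            for s in range(self.sites)
            for i in range(self.nodes_per_site)
        }
        got: list[NodeRef] = [m for t in self.trees for m in t.members]
        if len(got) != len(set(got)):
            raise MatchingConstraintError("a node appears in more than one tree")
        if set(got) != expected:
            raise MatchingConstraintError(
                "trees do not partition the full (site, node) set"
            )
        for t in self.trees:
            if len(t.members) != self.sites:
                raise MatchingConstraintError(
                    f"incomplete tree of size {len(t.members)} (expected {self.sites})"
                )

    def permutation_for_site(self, site: int) -> np.ndarray:
        """Old node index of ``site``'s member in each tree, in tree order.

        ``perm[j]`` is the node of ``site`` grouped into tree ``j``; reordering
        a site's layer rows by ``perm`` places matched neurons at a common index.
        """
        return np.array([t.member_for_site(site).node for t in self.trees])

    def to_dict(self) -> dict:
        return {
            "sites": self.sites,
            "nodes_per_site": self.nodes_per_site,
            "trees": [
                {
                    "members": [[m.site, m.node] for m in t.members],
                    "join_distances": t.join_distances,
                }
                for t in self.trees
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MatchingResult":
        trees = [
            MatchTree(
                [NodeRef(int(s), int(i)) for s, i in t["members"]],
                None if t.get("join_distances") is None else [float(x) for x in t["join_distances"]],
            )
            for t in d["trees"]
        ]
        return cls(trees, int(d["sites"]), int(d["nodes_per_site"]))

    @classmethod
    def from_json(cls, path) -> "MatchingResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def identity_matching(sites: int, nodes_per_site: int) -> MatchingResult:
    """The static index grouping: tree ``j`` holds node ``j`` of every site."""
    trees = [
        MatchTree([NodeRef(s, j) for s in range(sites)], None)
        for j in range(nodes_per_site)
    ]
    return MatchingResult(trees, sites, nodes_per_site)


# ---------------------------------------------------------------------------
# Greedy growth
# ---------------------------------------------------------------------------


def _pick_anchor(tree: MatchTree, anchor: str, rng) -> list[NodeRef]:
    """Members of ``tree`` eligible as distance anchors for one growth step."""
    if anchor == "all_members" or len(tree.members) == 1:
        return list(tree.members)
    if anchor == "seed_only":
        return [tree.seed]
    if anchor == "random_member":
        if rng is None:
            raise ValueError("random_member anchor requires an rng")
        idx = int(rng.integers(len(tree.members)))
        return [tree.members[idx]]
    raise ValueError(f"unknown anchor mode {anchor!r}; expected one of {ANCHOR_MODES}")


def tree_distance(
    v: NodeRef,
    tree: MatchTree,
    source: DistanceSource,
    anchor: str = "all_members",
    rng=None,
) -> tuple[float, NodeRef]:
    """Distance from candidate node ``v`` to a matching tree.

    ``all_members``: minimum distance to any tree member; ``seed_only``:
    distance to the seed; ``random_member``: distance to one member drawn
    uniformly via ``rng``.  For a singleton tree all modes coincide.  Returns
    the distance and the member realizing it (ties broken by lowest
    (site, node) member).
    """
    if not tree.members:
        raise ValueError("tree is empty")
    if v.site in tree.sites:
        raise MatchingConstraintError(
            f"candidate {v} is from site {v.site}, already present in the tree"
        )
    anchors = _pick_anchor(tree, anchor, rng)
    best: tuple[float, NodeRef] | None = None
    for m in sorted(anchors):
        d = source.distance(v, m)
        if best is None or d < best[0]:
            best = (d, m)
    assert best is not None
    return best


def grow_tree(
    tree: MatchTree,
    source: DistanceSource,
    remaining: Mapping[int, Iterable[int]],
    anchor: str = "all_members",
    rng=None,
) -> MatchTree:
    """Grow ``tree`` until every remaining site contributes exactly one node.

    Each step evaluates every unmatched node of every remaining site against
    the tree (per the anchor mode, with the anchor member drawn once per step
    for ``random_member``) and joins the global argmin; the matched site is
    then removed.  Ties break on lowest (site, node).  ``remaining`` maps each
    still-unmatched site to its pool of candidate node indices.
    """
    pools = {int(s): sorted(int(i) for i in nodes) for s, nodes in remaining.items()}
    if set(pools) & tree.sites:
        raise MatchingConstraintError("remaining sites overlap the tree's sites")
    members = list(tree.members)
    joins = list(tree.join_distances or [])
    while pools:
        for s, nodes in pools.items():
            if not nodes:
                raise MatchingConstraintError(
                    f"site {s} has no unmatched nodes left to grow the tree"
                )
        current = MatchTree(members, None)
        anchors = _pick_anchor(current, anchor, rng)
        best: tuple[float, NodeRef, NodeRef] | None = None
        for s in sorted(pools):
            for i in pools[s]:
                cand = NodeRef(s, i)
                for m in sorted(anchors):
                    d = source.distance(cand, m)
                    if best is None or d < best[0]:
                        best = (d, cand, m)
        assert best is not None
        d_star, v_star, _ = best
        members.append(v_star)
        joins.append(d_star)
        del pools[v_star.site]
    return MatchTree(members, joins)


def _global_min_pair(
    source: DistanceSource, pools: Mapping[int, set[int]]
) -> tuple[NodeRef, NodeRef]:
    """Globally closest remaining cross-site pair (tie: lexicographic)."""
    best: tuple[float, NodeRef, NodeRef] | None = None
    sites = sorted(pools)
    for ai, a_site in enumerate(sites):
        for b_site in sites[ai + 1:]:
            for i in sorted(pools[a_site]):
                for j in sorted(pools[b_site]):
                    a, b = NodeRef(a_site, i), NodeRef(b_site, j)
                    d = source.distance(a, b)
                    if best is None or d < best[0]:
                        best = (d, a, b)
    if best is None:
        raise ValueError("no cross-site pairs remain")
    return best[1], best[2]


def align_nodes(
    layer_weights,
    metric: str = "euclidean",
    anchor: str = "all_members",
    seeding: str = "random",
    rng=None,
) -> MatchingResult:
    """Partition one layer's neurons across all sites into matched trees.

    Trees are seeded and grown greedily until no unmatched node remains.
    ``seeding='random'`` starts each tree from a random unmatched site and
    node (the stochastic protocol); ``seeding='global_min'`` starts from the
    globally closest remaining cross-site pair (the deterministic variant
    that reproduces the three-site worked example).

    Parameters
    ----------
    layer_weights
        Per-site ``(n_nodes, n_dims)`` arrays, or a prebuilt
        :class:`DistanceSource`.
    anchor
        Node-to-tree distance mode: ``all_members`` (the full dynamic
        method), ``seed_only`` (fixed-anchor baseline), ``random_member``
        (random-anchor baseline).
    rng
        ``numpy.random.Generator`` (or seed) driving random seeding and
        random anchors.
    """
    if seeding not in SEEDING_MODES:
        raise ValueError(f"unknown seeding mode {seeding!r}; expected one of {SEEDING_MODES}")
    if anchor not in ANCHOR_MODES:
        raise ValueError(f"unknown anchor mode {anchor!r}; expected one of {ANCHOR_MODES}")
    source = _as_source(layer_weights, metric)
    rng = np.random.default_rng(rng)
    pools: dict[int, set[int]] = {
        s: set(range(source.nodes_per_site)) for s in range(source.n_sites)
    }
    trees: list[MatchTree] = []
    while any(pools.values()):
        if seeding == "random":
            sites_left = sorted(s for s, p in pools.items() if p)
            site = sites_left[int(rng.integers(len(sites_left)))]
            nodes_left = sorted(pools[site])
            seed = NodeRef(site, nodes_left[int(rng.integers(len(nodes_left)))])
        else:
            seed, _ = _global_min_pair(source, {s: p for s, p in pools.items() if p})
        pools[seed.site].discard(seed.node)
        tree = MatchTree([seed], [])
        remaining = {s: p for s, p in pools.items() if s != seed.site}
        tree = grow_tree(tree, source, remaining, anchor=anchor, rng=rng)
        for m in tree.members[1:]:
            pools[m.site].discard(m.node)
        trees.append(tree)
    return MatchingResult(trees, source.n_sites, source.nodes_per_site)


# ---------------------------------------------------------------------------
# Matching cost and exhaustive oracle
# ---------------------------------------------------------------------------


def _replay_tree_cost(members: Sequence[NodeRef], source: DistanceSource) -> float:
    # Prim replay from the lowest-site member: repeatedly join the nearest
    # remaining member.  Sum equals the MST weight of the member set, which is
    # also exactly what greedy growth records for the all-members anchor.
    ordered = sorted(members)
    in_tree = [ordered[0]]
    rest = set(ordered[1:])
    total = 0.0
    while rest:
        best: tuple[float, NodeRef] | None = None
        for cand in sorted(rest):
            for m in in_tree:
                d = source.distance(cand, m)
                if best is None or d < best[0]:
                    best = (d, cand)
        assert best is not None
        total += best[0]
        in_tree.append(best[1])
        rest.discard(best[1])
    return total


def matching_cost(result: MatchingResult, layer_weights, metric: str = "euclidean") -> float:
    """Total matching distance: sum over trees of their join distances.

    For trees carrying recorded join distances (greedy output) the recorded
    values are summed.  For groupings without a recorded growth (identity
    grouping, oracle output) the joins are replayed starting from each tree's
    lowest-site member, always joining the nearest remaining member; the
    replayed sum is the minimum-spanning-tree weight of the group and is
    invariant to member ordering.  Zero iff all grouped vectors are identical
    within each tree.
    """
    source = _as_source(layer_weights, metric)
    total = 0.0
    for tree in result.trees:
        if len(tree.members) != result.sites:
            raise MatchingConstraintError("matching contains an incomplete tree")
        if tree.join_distances is not None:
            total += float(sum(tree.join_distances))
        else:
            total += _replay_tree_cost(tree.members, source)
    return total


#: guard for the exhaustive oracle; beyond this the enumeration count
#: (nodes_per_site!)**(sites-1) is intractable.
OPTIMAL_MAX_SITES = 4
OPTIMAL_MAX_NODES = 6


def optimal_matching(layer_weights, metric: str = "euclidean") -> MatchingResult:
    """Exhaustive minimum-cost grouping (test oracle for small instances).

    Enumerates every grouping — all node permutations of sites ``2..Σ``
    against site ``1`` — and returns one minimizing :func:`matching_cost`
    (ties: first in deterministic enumeration order).  The search space grows
    as ``(n!)**(Σ-1)``, exponential in the number of sites, hence the hard
    size guard; this oracle exists to bound the greedy matcher in tests, not
    as an alternative alignment path.
    """
    source = _as_source(layer_weights, metric)
    sigma, n = source.n_sites, source.nodes_per_site
    if sigma > OPTIMAL_MAX_SITES or n > OPTIMAL_MAX_NODES:
        raise SizeLimitError(
            f"optimal_matching guard exceeded: sites={sigma} (max {OPTIMAL_MAX_SITES}), "
            f"nodes={n} (max {OPTIMAL_MAX_NODES})"
        )
    base = list(range(n))
    best_cost = np.inf
    best_perms: tuple[tuple[int, ...], ...] | None = None
    for perms in itertools.product(itertools.permutations(base), repeat=sigma - 1):
        cost = 0.0
        for j in base:
            members = [NodeRef(0, j)] + [
                NodeRef(s + 1, perms[s][j]) for s in range(sigma - 1)
            ]
            cost += _replay_tree_cost(members, source)
            if cost >= best_cost:
                break
        if cost < best_cost:
            best_cost = cost
            best_perms = perms
    assert best_perms is not None
    trees = [
        MatchTree(
            [NodeRef(0, j)] + [NodeRef(s + 1, best_perms[s][j]) for s in range(sigma - 1)],
            None,
        )
        for j in base
    ]
    return MatchingResult(trees, sigma, n)
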