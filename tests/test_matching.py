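"""Unit and property tests for greedy tree matching and its oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from feddna.matching import (
    DistanceTable,
    MatchTree,
    MatchingConstraintError,
    MatchingResult,
    NodeRef,
    SizeLimitError,
    WeightDistanceSource,
    align_nodes,
    build_distance_table,
    grow_tree,
    identity_matching,
    matching_cost,
    node_distance,
    optimal_matching,
    tree_distance,
)
from feddna.worked_example import label_of, three_site_source, three_site_tables

# ---------------------------------------------------------------------------
# node_distance
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "u, v, metric, expected",
    [
        ([0, 0, 0], [0, 0, 0], "euclidean", 0.0),
        ([0, 0], [3, 4], "euclidean", 5.0),
        ([1, 2, 3], [2, 0, 3], "manhattan", 3.0),
        ([1, 2, 3], [2, 0, 3], "euclidean", np.sqrt(5.0)),
    ],
)
def test_node_distance_known_values(u, v, metric, expected):
    assert node_distance(u, v, metric) == pytest.approx(expected)


def test_node_distance_validation():
    with pytest.raises(ValueError):
        node_distance([1, 2], [1, 2, 3], "euclidean")
    with pytest.raises(ValueError):
        node_distance([1, np.nan], [1, 2], "euclidean")
    with pytest.raises(ValueError):
        node_distance([1, 2], [1, 2], "cosine")


vectors = st.lists(
    st.floats(-50, 50, allow_nan=False, width=32), min_size=1, max_size=8
)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(data=st.data(), metric=st.sampled_from(["euclidean", "manhattan"]))
def test_metric_axioms(data, metric):
    """Identity, symmetry and the triangle inequality hold for both metrics."""
    n = data.draw(st.integers(1, 8))
    coord = st.floats(-50, 50, allow_nan=False, width=32)
    u, v, w = (
        np.array(data.draw(st.lists(coord, min_size=n, max_size=n)))
        for _ in range(3)
    )
    duv = node_distance(u, v, metric)
    assert node_distance(u, u, metric) == 0.0
    assert duv == pytest.approx(node_distance(v, u, metric))
    assert duv >= 0
    assert duv <= node_distance(u, w, metric) + node_distance(w, v, metric) + 1e-9


def test_distance_zero_iff_equal(rng):
    u = rng.normal(size=6)
    for metric in ("euclidean", "manhattan"):
        assert node_distance(u, u.copy(), metric) == 0.0
        assert node_distance(u, u + 1e-3, metric) > 0


# ---------------------------------------------------------------------------
# distance tables
# ---------------------------------------------------------------------------


def test_build_distance_table_matches_per_pair_recomputation(rng):
    a = [rng.normal(size=4) for _ in range(3)]
    b = [rng.normal(size=4) for _ in range(3)]
    table = build_distance_table(a, b, "manhattan")
    for i, j in itertools.product(range(3), range(3)):
        assert table.values[i, j] == pytest.approx(node_distance(a[i], b[j], "manhattan"))


def test_distance_table_identity_and_transpose(rng):
    a = [rng.normal(size=3) for _ in range(4)]
    same = build_distance_table(a, a, "euclidean")
    assert np.allclose(np.diag(same.values), 0.0)
    b = [rng.normal(size=3) for _ in range(4)]
    ab = build_distance_table(a, b, "euclidean")
    ba = build_distance_table(b, a, "euclidean")
    assert np.allclose(ab.values, ba.values.T)


def test_distance_table_csv_round_trip(tmp_path):
    table = three_site_tables()[0]
    path = tmp_path / "block.csv"
    table.to_csv(path)
    back = DistanceTable.from_csv(path)
    assert back.row_site == table.row_site and back.col_site == table.col_site
    assert back.row_labels == table.row_labels and back.col_labels == table.col_labels
    assert np.array_equal(back.values, table.values)


def test_build_distance_table_rejects_empty():
    with pytest.raises(ValueError):
        build_distance_table([], [[1.0]], "euclidean")


# ---------------------------------------------------------------------------
# tree_distance on the worked example
# ---------------------------------------------------------------------------

B = NodeRef(0, 1)
A_ = NodeRef(0, 0)
a = NodeRef(1, 0)
alpha = NodeRef(2, 0)
beta = NodeRef(2, 1)


def test_tree_distance_singleton_tree():
    src = three_site_source()
    d, member = tree_distance(a, MatchTree([B]), src)
    assert d == pytest.approx(0.11)
    assert member == B


def test_tree_distance_two_member_tree():
    src = three_site_source()
    d, _ = tree_distance(alpha, MatchTree([B, a], [0.11]), src)
    assert d == pytest.approx(0.13)


def test_tree_distance_seed_only_ignores_other_members():
    src = three_site_source()
    # seed a: d(beta, a) = 0.14 regardless of B being in the tree
    d, member = tree_distance(beta, MatchTree([a, B], [0.11]), src, anchor="seed_only")
    assert d == pytest.approx(0.14)
    assert member == a


def test_tree_distance_rejects_duplicate_site():
    src = three_site_source()
    with pytest.raises(MatchingConstraintError):
        tree_distance(A_, MatchTree([B, a], [0.11]), src)


def test_random_member_anchor_draws_from_tree(rng):
    src = three_site_source()
    seen = set()
    for _ in range(50):
        d, member = tree_distance(alpha, MatchTree([B, a], [0.11]), src,
                                  anchor="random_member", rng=rng)
        assert d == pytest.approx(src.distance(alpha, member))
        seen.add(member)
    assert seen == {B, a}


# ---------------------------------------------------------------------------
# grow_tree
# ---------------------------------------------------------------------------


def test_grow_tree_worked_example():
    src = three_site_source()
    tree = grow_tree(MatchTree([B, a], [0.11]), src, {2: [0, 1, 2]})
    assert set(tree.members) == {B, a, alpha}
    assert tree.join_distances == pytest.approx([0.11, 0.13])


def test_grow_tree_two_sites_is_pairwise_argmin(rng):
    layers = [rng.normal(size=(5, 3)) for _ in range(2)]
    src = WeightDistanceSource(layers, "euclidean")
    seed = NodeRef(0, 2)
    tree = grow_tree(MatchTree([seed], []), src, {1: range(5)})
    dists = [node_distance(layers[0][2], layers[1][j], "euclidean") for j in range(5)]
    assert tree.members[1] == NodeRef(1, int(np.argmin(dists)))
    assert tree.join_distances[0] == pytest.approx(min(dists))


def test_grow_tree_each_join_is_stepwise_minimum(rng):
    """Every recorded join equals the brute-force minimum over eligible joins."""
    layers = [rng.normal(size=(4, 6)) for _ in range(3)]
    src = WeightDistanceSource(layers, "manhattan")
    seed = NodeRef(0, 1)
    remaining = {1: list(range(4)), 2: list(range(4))}
    tree = grow_tree(MatchTree([seed], []), src, remaining)
    # replay: enumerate eligible (candidate, member) pairs at each step
    members = [seed]
    pools = {1: set(range(4)), 2: set(range(4))}
    for step, joined in enumerate(tree.members[1:]):
        eligible = [
            min(src.distance(NodeRef(s, i), m) for m in members)
            for s in sorted(pools)
            for i in sorted(pools[s])
        ]
        assert tree.join_distances[step] == pytest.approx(min(eligible))
        members.append(joined)
        pools.pop(joined.site)


def test_grow_tree_infeasible_site():
    src = three_site_source()
    with pytest.raises(MatchingConstraintError):
        grow_tree(MatchTree([B, a], [0.11]), src, {2: []})


# ---------------------------------------------------------------------------
# align_nodes
# ---------------------------------------------------------------------------


def test_align_worked_example_global_min():
    src = three_site_source()
    result = align_nodes(src, seeding="global_min")
    first = result.trees[0]
    assert {label_of(m.site, m.node) for m in first.members} == {"a", "B", "alpha"}
    assert first.join_distances == pytest.approx([0.11, 0.13])
    assert len(result.trees) == 3
    for tree in result.trees:
        assert len(tree.members) == 3


def test_align_identical_sites_zero_cost(rng):
    layer = rng.normal(size=(4, 5))
    layers = [layer.copy() for _ in range(3)]
    result = align_nodes(layers, seeding="random", rng=rng)
    assert matching_cost(result, layers) == 0.0
    # lowest-index tie-breaking groups identical vectors by index
    for tree in result.trees:
        assert len({m.node for m in tree.members}) == 1


def test_align_recovers_planted_permutation(rng):
    base = rng.normal(size=(5, 4))
    perms = [np.arange(5), rng.permutation(5), rng.permutation(5)]
    layers = [base[p] for p in perms]
    result = align_nodes(layers, metric="manhattan", rng=rng)
    assert matching_cost(result, layers, "manhattan") == 0.0
    for tree in result.trees:
        # every member of a tree points back at the same base node
        base_nodes = {perms[m.site][m.node] for m in tree.members}
        assert len(base_nodes) == 1


@pytest.mark.parametrize("seeding", ["random", "global_min"])
@pytest.mark.parametrize("anchor", ["all_members", "seed_only", "random_member"])
def test_align_partition_invariant(rng, seeding, anchor):
    sigma, n = 4, 5
    layers = [rng.normal(size=(n, 3)) for _ in range(sigma)]
    result = align_nodes(layers, anchor=anchor, seeding=seeding, rng=rng)
    refs = [m for t in result.trees for m in t.members]
    assert len(refs) == sigma * n
    assert len(set(refs)) == sigma * n
    for tree in result.trees:
        assert sorted(m.site for m in tree.members) == list(range(sigma))


def test_align_rejects_unequal_node_counts(rng):
    with pytest.raises(ValueError):
        align_nodes([rng.normal(size=(4, 3)), rng.normal(size=(5, 3))])


def test_align_reproducible_with_seed(rng):
    layers = [rng.normal(size=(4, 3)) for _ in range(3)]
    r1 = align_nodes(layers, rng=np.random.default_rng(5))
    r2 = align_nodes(layers, rng=np.random.default_rng(5))
    assert r1.to_dict() == r2.to_dict()


# ---------------------------------------------------------------------------
# matching_cost
# ---------------------------------------------------------------------------


def test_matching_cost_worked_example_first_tree():
    src = three_site_source()
    result = align_nodes(src, seeding="global_min")
    assert sum(result.trees[0].join_distances) == pytest.approx(0.24)


def test_matching_cost_identity_on_identical_sites(rng):
    layer = rng.normal(size=(3, 4))
    layers = [layer.copy() for _ in range(3)]
    assert matching_cost(identity_matching(3, 3), layers) == 0.0


def test_matching_cost_invariant_under_consistent_relabeling(rng):
    layers = [rng.normal(size=(4, 3)) for _ in range(3)]
    cost = matching_cost(align_nodes(layers, rng=np.random.default_rng(1)), layers)
    perms = [rng.permutation(4) for _ in range(3)]
    relabeled = [lay[p] for lay, p in zip(layers, perms)]
    cost_rel = matching_cost(
        align_nodes(relabeled, rng=np.random.default_rng(1)), relabeled
    )
    assert cost_rel == pytest.approx(cost)


def test_matching_cost_replay_matches_recorded_for_greedy(rng):
    """Replaying a greedy tree without its recorded joins gives the same sum."""
    layers = [rng.normal(size=(4, 3)) for _ in range(3)]
    result = align_nodes(layers, rng=rng)
    stripped = MatchingResult(
        [MatchTree(list(t.members), None) for t in result.trees],
        result.sites,
        result.nodes_per_site,
    )
    assert matching_cost(stripped, layers) == pytest.approx(matching_cost(result, layers))


def test_matching_cost_rejects_incomplete_tree(rng):
    layers = [rng.normal(size=(2, 3)) for _ in range(3)]
    bad = MatchingResult.__new__(MatchingResult)  # bypass validation on purpose
    bad.trees = [MatchTree([NodeRef(0, 0)], [])]
    bad.sites = 3
    bad.nodes_per_site = 2
    with pytest.raises(MatchingConstraintError):
        matching_cost(bad, layers)


# ---------------------------------------------------------------------------
# optimal matching oracle
# ---------------------------------------------------------------------------


def test_optimal_identical_sites_cost_zero(rng):
    layer = rng.normal(size=(3, 4))
    layers = [layer.copy() for _ in range(3)]
    assert matching_cost(optimal_matching(layers), layers) == 0.0


def test_optimal_two_sites_equals_assignment_solver(rng):
    """For two sites the oracle must equal the exhaustive min-cost assignment."""
    for _ in range(5):
        layers = [rng.normal(size=(4, 3)) for _ in range(2)]
        cost_mat = np.array(
            [[node_distance(layers[0][i], layers[1][j], "euclidean") for j in range(4)]
             for i in range(4)]
        )
        ri, ci = linear_sum_assignment(cost_mat)
        expected = cost_mat[ri, ci].sum()
        got = matching_cost(optimal_matching(layers), layers)
        assert got == pytest.approx(expected)


def test_greedy_never_beats_oracle(rng):
    for _ in range(10):
        sigma = int(rng.integers(2, 4))
        n = int(rng.integers(2, 5))
        layers = [rng.normal(size=(n, 3)) for _ in range(sigma)]
        greedy = matching_cost(align_nodes(layers, rng=rng), layers)
        optimal = matching_cost(optimal_matching(layers), layers)
        assert greedy >= optimal - 1e-9


def test_optimal_guard():
    layers = [np.zeros((7, 2)) for _ in range(2)]
    with pytest.raises(SizeLimitError):
        optimal_matching(layers)
    layers = [np.zeros((2, 2)) for _ in range(5)]
    with pytest.raises(SizeLimitError):
        optimal_matching(layers)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_matching_result_json_round_trip(tmp_path, rng):
    layers = [rng.normal(size=(3, 4)) for _ in range(3)]
    result = align_nodes(layers, rng=rng)
    path = tmp_path / "matching.json"
    result.to_json(path)
    back = MatchingResult.from_json(path)
    assert back.to_dict() == result.to_dict()


def test_match_tree_rejects_same_site_members():
    with pytest.raises(MatchingConstraintError):
        MatchTree([NodeRef(0, 0), NodeRef(0, 1)])
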