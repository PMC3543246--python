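"""Signed/directed modularity, resolution screening, Wallace comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trntopo.mesoscale import (
    Partition,
    asymmetric_wallace,
    confusion_matrix,
    detect_plateaus,
    functional_node_filter,
    modularity,
    optimize_partition,
    rescale,
    screen_resolution,
)
from trntopo.model import NetworkView
from trntopo.synth import planted_partition_benchmark

from conftest import build_net, view_from_edges, hierarchical_toy_view


def brute_force_modularity(matrix, labels):
    """Literal pairwise-sum evaluation of the signed directed quality."""
    pos = np.clip(matrix, 0, None)
    neg = np.clip(-matrix, 0, None)
    total = pos.sum() + neg.sum()
    if total == 0:
        return 0.0
    q = 0.0
    for w_s, sgn in ((pos, 1.0), (neg, -1.0)):
        w = w_s.sum()
        if w == 0:
            continue
        part = 0.0
        for i in range(len(matrix)):
            for j in range(len(matrix)):
                if labels[i] == labels[j]:
                    part += w_s[i, j] / w - w_s[i].sum() * w_s[:, j].sum() / w**2
        q += sgn * w * part / total
    return q


def all_partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    head = items[0]
    for blocks in all_partitions(items[1:]):
        for i in range(len(blocks)):
            yield blocks[:i] + [[head] + blocks[i]] + blocks[i + 1:]
        yield [[head]] + blocks


# ---------------------------------------------------------------------------
# modularity values
# ---------------------------------------------------------------------------


def test_single_community_partition_has_zero_q():
    views = [
        view_from_edges([(0, 1), (1, 2), (2, 0), (0, 0)]),
        hierarchical_toy_view(),
    ]
    for v in views:
        part = Partition({n: 0 for n in v.nodes})
        assert modularity(v, part).q_total == pytest.approx(0.0, abs=1e-12)


def test_two_disjoint_triangles_give_half():
    m = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        m[i, j] = m[j, i] = 1.0
    v = NetworkView("UU", tuple("abcdef"), m)
    part = Partition(dict(zip("abcdef", [0, 0, 0, 1, 1, 1])))
    val = modularity(v, part)
    assert val.q_total == pytest.approx(0.5)
    assert val.q_total == pytest.approx(brute_force_modularity(m, [0, 0, 0, 1, 1, 1]))


def test_negative_links_dissolve_communities():
    # inhibitions inside a community are penalized; splitting relieves it
    m = np.zeros((4, 4))
    m[0, 1] = -1.0
    m[2, 3] = -1.0
    v = NetworkView("DS", ("a", "b", "c", "d"), m)
    together = modularity(v, Partition({"a": 0, "b": 0, "c": 1, "d": 1})).q_total
    apart = modularity(v, Partition({"a": 0, "b": 1, "c": 2, "d": 3})).q_total
    assert together < 0
    assert apart > together
    for labels in ([0, 0, 1, 1], [0, 1, 2, 3]):
        assert modularity(v, Partition(dict(zip("abcd", labels)))).q_total == (
            pytest.approx(brute_force_modularity(m, labels))
        )


def test_recomposition_identity_and_oracle_on_random_signed_views():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(3, 8))
        m = (rng.random((n, n)) < 0.5) * rng.choice([1.0, -1.0], size=(n, n))
        labels = rng.integers(0, 3, size=n)
        v = NetworkView("DU", tuple(f"n{i}" for i in range(n)), m)
        val = modularity(v, Partition({f"n{i}": int(labels[i]) for i in range(n)}))
        w = val.w_pos + val.w_neg
        recomposed = (val.w_pos * val.q_pos - val.w_neg * val.q_neg) / w
        assert val.q_total == pytest.approx(recomposed, abs=1e-12)
        assert val.q_total == pytest.approx(brute_force_modularity(m, labels), abs=1e-9)


def test_modularity_missing_node_errors():
    v = view_from_edges([(0, 1)])
    with pytest.raises(KeyError):
        modularity(v, Partition({v.nodes[0]: 0}))


def test_rescale_shifts_only_the_diagonal():
    v = view_from_edges([(0, 1), (1, 2)], n=3)
    assert np.array_equal(rescale(v, 0.0).matrix, v.matrix)
    r2 = rescale(NetworkView("DU", ("a", "b", "c"), np.zeros((3, 3))), 2.0)
    assert np.array_equal(r2.matrix, 2.0 * np.eye(3))
    rneg = rescale(v, -0.5)
    assert np.allclose(np.diag(rneg.matrix), -0.5)
    off = ~np.eye(3, dtype=bool)
    assert np.array_equal(rneg.matrix[off], v.matrix[off])


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def two_cliques_view(k=5):
    n = 2 * k
    m = np.zeros((n, n))
    for g in (range(k), range(k, n)):
        for i in g:
            for j in g:
                if i != j:
                    m[i, j] = 1.0
    return NetworkView("UU", tuple(f"n{i}" for i in range(n)), m)


def test_optimizer_separates_disjoint_cliques():
    part, val = optimize_partition(two_cliques_view(), seed=0)
    groups = sorted(sorted(g) for g in part.communities().values())
    assert groups == [[f"n{i}" for i in range(5)], [f"n{i}" for i in range(5, 10)]]
    assert val.q_total == pytest.approx(0.5)


def test_optimizer_matches_exhaustive_search_on_8_nodes():
    rng = np.random.default_rng(0)
    m = (rng.random((8, 8)) < 0.3) * rng.choice([1.0, 1.0, -1.0], size=(8, 8))
    np.fill_diagonal(m, 0.0)
    ids = tuple("abcdefgh")
    v = NetworkView("DU", ids, m)
    best = max(
        brute_force_modularity(m, [next(k for k, blk in enumerate(blocks) if n in blk)
                                   for n in ids])
        for blocks in all_partitions(ids)
    )
    _, val = optimize_partition(v, seed=0)
    assert val.q_total == pytest.approx(best, abs=1e-9)


def test_optimizer_never_below_single_community():
    rng = np.random.default_rng(3)
    for seed in range(3):
        n = 12
        m = (rng.random((n, n)) < 0.25) * rng.choice([1.0, -1.0], size=(n, n))
        v = NetworkView("DU", tuple(f"n{i}" for i in range(n)), m)
        _, val = optimize_partition(v, seed=seed)
        assert val.q_total >= -1e-12


def test_optimizer_is_seed_deterministic():
    v, _ = planted_partition_benchmark(seed=1)
    p1, q1 = optimize_partition(v, seed=9)
    p2, q2 = optimize_partition(v, seed=9)
    assert p1.assignment == p2.assignment
    assert q1 == q2


def test_planted_partition_recovery():
    """Strong planted structure (p_in=0.3 vs p_out=0.01) is recovered."""
    successes = 0
    for seed in range(10):
        view, planted = planted_partition_benchmark(4, 25, 0.3, 0.01, seed=seed)
        part, _ = optimize_partition(view, seed=seed)
        aw = asymmetric_wallace(part, planted)
        successes += aw is not None and aw >= 0.9
    assert successes >= 9


# ---------------------------------------------------------------------------
# screening and plateaus
# ---------------------------------------------------------------------------


def test_hierarchical_toy_screen_shows_both_levels(hierarchical_toy):
    screen = screen_resolution(hierarchical_toy, r_min=-4.0, r_max=1.0,
                               n_points=60, seed=0)
    plateaus = detect_plateaus(screen, min_run=4)
    assert {p.n_communities for p in plateaus} == {2, 4}
    rs = [p.r for p in screen.points]
    assert rs == sorted(rs)
    assert screen.points[0].normalized_r == 0.0
    assert screen.points[-1].normalized_r == 1.0


def test_single_clique_is_one_community_for_small_r():
    k = 6
    m = np.ones((k, k)) - np.eye(k)
    v = NetworkView("UU", tuple(f"n{i}" for i in range(k)), m)
    # below r = 1 the clique's singleton split cannot beat one community
    screen = screen_resolution(v, r_min=0.0, r_max=0.9, n_points=10, seed=0)
    assert all(nc == 1 for nc in screen.n_communities())
    assert len(screen) == 10  # grid size honored


@pytest.mark.parametrize(
    "ncs, min_run, expected",
    [
        ([1, 1, 1, 2, 2, 3], 2, [(0, 2, 1), (3, 4, 2)]),
        ([1, 2, 3, 4, 5], 2, []),
    ],
)
def test_detect_plateaus_by_definition(ncs, min_run, expected, monkeypatch):
    from trntopo.mesoscale import MesoscaleScreen, ScreenPoint, ModularityValue

    pts = tuple(
        ScreenPoint(
            r=float(i), normalized_r=i / max(1, len(ncs) - 1),
            partition=Partition({f"n{j}": j % nc for j in range(6)}),
            modularity=ModularityValue(0, 0, 0, 1, 0),
        )
        for i, nc in enumerate(ncs)
    )
    plats = detect_plateaus(MesoscaleScreen(points=pts), min_run=min_run)
    assert [(p.start_index, p.end_index, p.n_communities) for p in plats] == expected


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------


def test_confusion_matrix_identical_partitions_is_diagonal():
    a = Partition({"1": "x", "2": "x", "3": "y", "4": "y"})
    cm = confusion_matrix(a, a)
    assert np.array_equal(cm.counts, np.diag(np.diag(cm.counts)))
    assert cm.total == 4


def test_confusion_matrix_crossed_pairs():
    a = Partition({"1": 0, "2": 0, "3": 1, "4": 1})
    b = Partition({"1": 0, "3": 0, "2": 1, "4": 1})
    cm = confusion_matrix(a, b)
    assert np.array_equal(cm.counts, np.ones((2, 2), dtype=int))


def test_confusion_matrix_sums_are_cluster_sizes():
    rng = np.random.default_rng(5)
    nodes = [f"n{i}" for i in range(50)]
    a = Partition({n: int(rng.integers(0, 5)) for n in nodes})
    b = Partition({n: int(rng.integers(0, 3)) for n in nodes})
    cm = confusion_matrix(a, b)
    sizes_a = sorted(len(v) for v in a.communities().values())
    assert sorted(cm.row_sums.tolist()) == sizes_a
    assert cm.total == 50


def test_confusion_matrix_disjoint_nodes_errors():
    with pytest.raises(ValueError, match="share no nodes"):
        confusion_matrix(Partition({"a": 0}), Partition({"b": 0}))


def aw_pair_probability(a: Partition, b: Partition):
    """Direct enumeration of co-clustered pairs (the definition)."""
    common = a.nodes & b.nodes
    pairs = [
        (x, y)
        for x, y in itertools.combinations(sorted(common), 2)
        if a.assignment[x] == a.assignment[y]
    ]
    if not pairs:
        return None
    kept = sum(1 for x, y in pairs if b.assignment[x] == b.assignment[y])
    return kept / len(pairs)


def test_asymmetric_wallace_examples():
    a = Partition({"1": 0, "2": 0, "3": 1, "4": 1, "5": 1})
    assert asymmetric_wallace(a, a) == pytest.approx(1.0)
    a2 = Partition({"1": 0, "2": 0, "3": 1, "4": 1})
    whole = Partition({k: 0 for k in "1234"})
    assert asymmetric_wallace(a2, whole) == pytest.approx(1.0)
    assert asymmetric_wallace(whole, a2) == pytest.approx(2 / 6)


def test_asymmetric_wallace_undefined_for_all_singletons():
    a = Partition({"1": 0, "2": 1, "3": 2})
    b = Partition({"1": 0, "2": 0, "3": 0})
    assert asymmetric_wallace(a, b) is None


@given(
    st.lists(st.tuples(st.integers(0, 4), st.integers(0, 3)),
             min_size=2, max_size=30)
)
def test_asymmetric_wallace_equals_pair_probability(assignments):
    nodes = [f"n{i}" for i in range(len(assignments))]
    a = Partition({n: ca for n, (ca, _) in zip(nodes, assignments)})
    b = Partition({n: cb for n, (_, cb) in zip(nodes, assignments)})
    expected = aw_pair_probability(a, b)
    got = asymmetric_wallace(a, b)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


@given(
    st.lists(st.tuples(st.integers(0, 3), st.integers(0, 2)),
             min_size=4, max_size=25),
    st.integers(0, 10_000),
)
def test_asymmetric_wallace_non_increasing_under_splitting_b(assignments, salt):
    nodes = [f"n{i}" for i in range(len(assignments))]
    a = Partition({n: ca for n, (ca, _) in zip(nodes, assignments)})
    b = Partition({n: cb for n, (_, cb) in zip(nodes, assignments)})
    before = asymmetric_wallace(a, b)
    if before is None:
        return
    # split each B-cluster in two deterministic halves
    rng = np.random.default_rng(salt)
    split = {
        n: (cb, int(rng.integers(0, 2))) for n, cb in b.assignment.items()
    }
    after = asymmetric_wallace(a, Partition(split))
    assert after <= before + 1e-12


# ---------------------------------------------------------------------------
# functional filter
# ---------------------------------------------------------------------------


def test_functional_filter_excludes_unannotated_and_regulatory_labels():
    cats = {
        "a": "cat_1", "b": "cat_2", "c": "unknown",
        "d": "conserved_hypothetical", "e": "regulatory_proteins",
        "f": "information_pathways", "g": "cat_1",
    }
    net = build_net(
        [("a", "b"), ("c", "d"), ("e", "f"), ("a", "g")], categories=cats
    )
    assert functional_node_filter(net) == {"a", "b", "g"}


def test_functional_filter_all_unknown_is_empty():
    net = build_net([("a", "b")], categories={"a": "unknown", "b": "unknown"})
    assert functional_node_filter(net) == set()


def test_functional_filter_without_annotations_errors():
    net = build_net([("a", "b")])
    with pytest.raises(ValueError, match="annotation"):
        functional_node_filter(net)
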