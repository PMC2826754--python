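import math
import random

import pytest

from netflow import (
    ProbNetwork,
    QuerySet,
    SyntheticSpec,
    adapt_threshold,
    budgeted_query,
    build_cluster_graph,
    build_hierarchy,
    cluster_max_bound,
    generate_network,
    netflow_score,
    rank_candidates,
    threshold_query,
)
from netflow.clustering import Cluster, hierarchy_from_flat

from conftest import make_random_net


@pytest.fixture
def two_cluster_net():
    """Two 7-member clusters joined by three crossing edges (0.3, 0.7, 0.5),
    with a query protein attached to the first cluster."""
    edges = []
    for pre in ("a", "b"):
        for i in range(6):
            edges.append((f"{pre}0", f"{pre}{i + 1}", 0.9))
    edges += [("a1", "b1", 0.3), ("a2", "b2", 0.7), ("a3", "b3", 0.5)]
    edges += [("qq", "a0", 0.8)]
    net = ProbNetwork.from_edges(edges)
    clusters = [
        ("cA", frozenset(f"a{i}" for i in range(7))),
        ("cB", frozenset(f"b{i}" for i in range(7))),
    ]
    return net, clusters, QuerySet(["qq"])


class TestClusterGraph:
    def test_crossing_edges_summarised_by_max_and_count(self, two_cluster_net):
        net, clusters, q = two_cluster_net
        cg = build_cluster_graph(net, clusters, q)
        assert cg.edges[("cA", "cB")] == (0.7, 3)
        assert cg.edges[("cA", "qq")] == (0.8, 1)

    def test_singleton_clustering_is_isomorphic_to_network(self):
        rng = random.Random(8)
        net = make_random_net(rng, max_nodes=10, max_edges=20)
        nodes = sorted(net.nodes)
        q = QuerySet(nodes[:1])
        singles = [(f"s_{v}", frozenset([v])) for v in nodes[1:]]
        cg = build_cluster_graph(net, singles, q)
        assert all(m == 1 for _, m in cg.edges.values())
        assert len(cg.edges) == net.number_of_edges()

    def test_no_crossing_edges_no_cluster_edge(self):
        net = ProbNetwork.from_edges(
            [("a1", "a2", 0.5), ("b1", "b2", 0.5), ("qq", "a1", 0.5)]
        )
        cg = build_cluster_graph(
            net,
            [("cA", frozenset(["a1", "a2"])), ("cB", frozenset(["b1", "b2"]))],
            QuerySet(["qq"]),
        )
        assert ("cA", "cB") not in cg.edges

    def test_overlapping_clusters_rejected(self, two_cluster_net):
        net, clusters, q = two_cluster_net
        bad = clusters + [("cC", frozenset(["a1", "b1"]))]
        with pytest.raises(ValueError, match="overlap"):
            build_cluster_graph(net, bad, q)


class TestClusterMaxBound:
    def test_bandwidth_exponentiates_path_failure(self):
        """Two parallel 2-edge routes collapse to one cluster path of
        bandwidth 2: bound = 1 - 0.64^2."""
        edges = [
            ("qq", "a1", 0.6), ("qq", "a2", 0.6),
            ("a1", "b1", 0.6), ("a2", "b2", 0.6),
        ]
        net = ProbNetwork.from_edges(edges)
        q = QuerySet(["qq"])
        clusters = [
            ("cA", frozenset(["a1", "a2"])),
            ("cB", frozenset(["b1", "b2"])),
        ]
        cg = build_cluster_graph(net, clusters, q)
        cb = cluster_max_bound(cg, q, "cB")
        assert cb.bandwidths == (2,)
        assert cb.max_bound == pytest.approx(1 - 0.64**2)

    def test_unreachable_target_bound_zero(self):
        net = ProbNetwork.from_edges([("qq", "a1", 0.5), ("b1", "b2", 0.5)])
        cg = build_cluster_graph(
            net,
            [("cA", frozenset(["a1"])), ("cB", frozenset(["b1", "b2"]))],
            QuerySet(["qq"]),
        )
        assert cluster_max_bound(cg, QuerySet(["qq"]), "cB").max_bound == 0.0

    def test_singleton_clustering_reduces_to_flow_bound(self):
        """With every node its own cluster all multiplicities are 1 and the
        bandwidth-modified bound equals the plain flow bound."""
        rng = random.Random(77)
        for _ in range(5):
            net = make_random_net(rng, max_nodes=15, max_edges=30)
            nodes = sorted(net.nodes)
            q = QuerySet(nodes[:2])
            singles = [(f"s_{v}", frozenset([v])) for v in nodes[2:]]
            cg = build_cluster_graph(net, singles, q)
            for sid, ms in singles:
                v = next(iter(ms))
                assert cluster_max_bound(cg, q, sid).max_bound == pytest.approx(
                    netflow_score(net, q, v).bound, abs=1e-9
                )

    def test_dominates_member_bounds_on_random_instances(self):
        """Empirical admissibility: the cluster bound should upper-bound
        every member's flow bound; rare violations are counted."""
        rng = random.Random(42)
        checked = violations = 0
        for _ in range(40):
            net = make_random_net(rng, max_nodes=25, max_edges=60,
                                  weight_range=(0.05, 0.95))
            nodes = sorted(net.nodes)
            q = QuerySet(rng.sample(nodes, rng.randint(1, 3)))
            h = build_hierarchy(net, leaf_size=4, level_sizes=(4, 16, math.inf))
            cg = build_cluster_graph(net, h.leaves(), q)
            for leaf in h.leaves():
                mem = leaf.members - q.members
                if not mem or leaf.id not in cg.vertices:
                    continue
                cb = cluster_max_bound(cg, q, leaf.id).max_bound
                for m in mem:
                    checked += 1
                    if cb < netflow_score(net, q, m).bound - 1e-9:
                        violations += 1
        assert checked > 200
        assert violations / checked < 0.01


@pytest.fixture(scope="module")
def planted_scene():
    spec = SyntheticSpec(n_nodes=120, n_complexes=5, seed=21)
    net, complexes = generate_network(spec)
    h = build_hierarchy(net, leaf_size=8, level_sizes=(8, 32, math.inf))
    members = sorted(complexes[0].members)
    q = QuerySet(members[1:])
    return net, h, q


class TestThresholdQuery:
    def test_matches_exhaustive_filtering(self, planted_scene):
        net, h, q = planted_scene
        exhaustive = rank_candidates(net, q)
        n_nonquery = len(net.nodes) - len(q.members)
        for thr in (0.05, 0.2):
            rep = threshold_query(net, h, q, thr)
            want = sorted(r.sink for r in exhaustive if r.bound >= thr)
            got = sorted(r.sink for r in rep.answers)
            assert got == want
            assert rep.flow_instances_executed < n_nonquery
            assert all(r.bound >= thr for r in rep.answers)

    def test_threshold_above_all_roots_prunes_everything(self):
        spec = SyntheticSpec(n_nodes=80, weight_law=("fixed", 0.2),
                             n_complexes=0, seed=1)
        net, _ = generate_network(spec)
        h = build_hierarchy(net, leaf_size=8, level_sizes=(8, 32, math.inf))
        q = QuerySet(sorted(net.nodes)[:2])
        rep = threshold_query(net, h, q, 0.999)
        assert rep.answers == []
        assert rep.flow_instances_executed == 0

    def test_singleton_leaves_exact_equivalence(self):
        rng = random.Random(13)
        net = make_random_net(rng, max_nodes=15, max_edges=30)
        nodes = sorted(net.nodes)
        q = QuerySet(nodes[:2])
        singles = [
            Cluster(id=f"s{i}", members=frozenset([v]))
            for i, v in enumerate(nodes[2:])
        ]
        h = hierarchy_from_flat(singles)
        exhaustive = rank_candidates(net, q)
        for thr in (0.01, 0.1, 0.5):
            rep = threshold_query(net, h, q, thr)
            assert sorted(r.sink for r in rep.answers) == sorted(
                r.sink for r in exhaustive if r.bound >= thr
            )

    def test_work_non_increasing_in_threshold(self, planted_scene):
        net, h, q = planted_scene
        flows = [
            threshold_query(net, h, q, thr).flow_instances_executed
            for thr in (0.02, 0.1, 0.3)
        ]
        assert flows == sorted(flows, reverse=True)

    def test_strict_recompute_same_answers(self, planted_scene):
        net, h, q = planted_scene
        a = threshold_query(net, h, q, 0.1)
        b = threshold_query(net, h, q, 0.1, strict=True)
        assert [r.sink for r in a.answers] == [r.sink for r in b.answers]


class TestAdaptiveThreshold:
    @pytest.mark.parametrize(
        "policy, n_answers, expected",
        [("none", 0, 0.04), ("halve", 0, 0.02), ("halve", 3, 0.04)],
    )
    def test_policy_arithmetic(self, policy, n_answers, expected):
        assert adapt_threshold(0.04, policy, n_answers) == pytest.approx(expected)

    def test_target_k_reaches_k_answers(self, planted_scene):
        net, h, q = planted_scene
        rep = threshold_query(net, h, q, 0.9, adapt="target_k", target_k=5)
        assert len(rep.answers) >= 5
        assert rep.threshold < 0.9

    def test_resumed_search_matches_fresh_run(self, planted_scene):
        """Cache soundness: adapting down to a final threshold returns the
        same answers as a fresh query at that threshold."""
        net, h, q = planted_scene
        adapted = threshold_query(net, h, q, 0.9, adapt="halve")
        fresh = threshold_query(net, h, q, adapted.threshold)
        assert [r.sink for r in adapted.answers] == [r.sink for r in fresh.answers]


class TestBudgetedQuery:
    def test_full_budget_reproduces_exhaustive_ranking(self, planted_scene):
        net, h, q = planted_scene
        rep = budgeted_query(net, h, q, 1.0)
        exhaustive = rank_candidates(net, q)
        assert [(r.sink, r.bound) for r in rep.answers] == [
            (r.sink, r.bound) for r in exhaustive
        ]

    def test_flow_budget_respected(self, planted_scene):
        net, h, q = planted_scene
        n_nonquery = len(net.nodes) - len(q.members)
        rep = budgeted_query(net, h, q, 0.1)
        assert rep.flow_instances_executed == math.ceil(0.1 * n_nonquery)

    def test_budget_finds_planted_member_in_most_replicates(self):
        """The hidden complex member should be among the verified top
        fraction in the large majority of seeded replicates."""
        hits = total = 0
        for seed in range(15):
            spec = SyntheticSpec(n_nodes=100, n_complexes=4, seed=seed)
            net, complexes = generate_network(spec)
            h = build_hierarchy(net, leaf_size=8, level_sizes=(8, 32, math.inf))
            cx = complexes[seed % len(complexes)]
            members = sorted(cx.members)
            q = QuerySet(members[1:])
            rep = budgeted_query(net, h, q, 0.1)
            total += 1
            hits += any(r.sink == members[0] for r in rep.answers)
        assert hits / total >= 0.7
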