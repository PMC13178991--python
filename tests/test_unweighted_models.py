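import math

import numpy as np
import pytest
from scipy import stats as sps

from netbackbone.generators import gen_preferential_attachment, gen_sbm
from netbackbone.graph_core import Network
from netbackbone.retain import EdgeStatistics
from netbackbone.unweighted_models import (
    backbone_from_unweighted,
    escore,
    filter_edges,
    normalize_scores,
    simmelian_redundancy,
    umst,
)

from conftest import random_unweighted, random_weighted


def complete_graph(n):
    return Network(
        [f"n{i}" for i in range(n)],
        [(i, j) for i in range(n) for j in range(i + 1, n)],
    )


def brute_force_scores(net, metric):
    """Independent straightforward recount of each metric."""
    nb = net.neighbor_sets()
    k = net.degrees()
    n = net.n_nodes
    out = []
    for u, v in net.edges:
        cu, cv = nb[u] | {u}, nb[v] | {v}
        common = len(nb[u] & nb[v])
        if metric == "jaccard":
            out.append(len(cu & cv) / len(cu | cv))
        elif metric == "triangles":
            out.append(common)
        elif metric == "meetmin":
            out.append(len(cu & cv) / min(k[u], k[v]))
        elif metric == "geometric":
            out.append(len(cu & cv) ** 2 / (k[u] * k[v]))
        elif metric == "hyper":
            out.append(1.0 - sps.hypergeom.sf(common - 1, n, k[v], k[u]))
        elif metric == "quadrangles":
            q = 0
            for b in nb[u] - {v}:
                for a in nb[v] - {u}:
                    if a != b and (min(a, b), max(a, b)) in set(net.edges):
                        q += 1
            out.append(q)
    return np.array(out, dtype=float)


class TestEscore:
    def test_triangle_jaccard_all_one(self):
        stats = escore(complete_graph(3), "jaccard")
        np.testing.assert_allclose(stats.scores, 1.0)

    def test_star_triangles_zero(self):
        star = Network(["c", "a", "b"], [(0, 1), (0, 2)])
        stats = escore(star, "triangles")
        np.testing.assert_array_equal(stats.scores, 0.0)

    def test_degree_is_directional(self):
        path = Network(["a", "b", "c"], [(0, 1), (1, 2)])
        stats = escore(path, "degree")
        # a's view of (a,b) is k_b = 2; b's view is k_a = 1
        assert stats.endpoint_scores[0, 0] == 2
        assert stats.endpoint_scores[0, 1] == 1

    @pytest.mark.parametrize(
        "metric", ["jaccard", "triangles", "meetmin", "geometric", "hyper"]
    )
    def test_brute_force_oracle(self, metric):
        net = random_unweighted(30, 0.2, seed=1)
        stats = escore(net, metric)
        np.testing.assert_allclose(stats.scores, brute_force_scores(net, metric), atol=1e-12)

    def test_quadrangles_ratio_from_counts(self):
        net = random_unweighted(20, 0.3, seed=2)
        q = brute_force_scores(net, "quadrangles")
        qnode = np.zeros(net.n_nodes)
        for e, (u, v) in enumerate(net.edges):
            qnode[u] += q[e]
            qnode[v] += q[e]
        expected = np.array(
            [
                q[e] / math.sqrt(qnode[u] * qnode[v]) if qnode[u] * qnode[v] > 0 else 0.0
                for e, (u, v) in enumerate(net.edges)
            ]
        )
        stats = escore(net, "quadrangles")
        np.testing.assert_allclose(stats.scores, expected, atol=1e-12)

    def test_random_is_seeded(self):
        net = random_unweighted(15, 0.4, seed=3)
        a = escore(net, "random", seed=9).scores
        b = escore(net, "random", seed=9).scores
        c = escore(net, "random", seed=10).scores
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_weighted_input_rejected(self):
        with pytest.raises(ValueError):
            escore(random_weighted(10, 0.5, seed=0), "jaccard")


class TestNormalize:
    def test_rank_with_tie_break(self):
        # node 0 has three incident edges scored 0.9, 0.5, 0.5
        net = Network(["x", "a", "b", "c"], [(0, 1), (0, 2), (0, 3)])
        stats = EdgeStatistics(
            edges=list(net.edges), model="t", network=net,
            scores=np.array([0.9, 0.5, 0.5]),
        )
        ranked = normalize_scores(stats, "rank")
        assert list(ranked.endpoint_scores[:, 0]) == [1.0, 2.0, 3.0]

    def test_none_identity(self):
        net = random_unweighted(10, 0.4, seed=4)
        stats = escore(net, "jaccard")
        assert normalize_scores(stats, "none") is stats

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            normalize_scores(escore(random_unweighted(5, 0.5, seed=0), "jaccard"), "zscore")

    def test_permutation_equivariance(self):
        # relabeling nodes permutes ranks identically when scores are untied
        net = random_unweighted(12, 0.5, seed=5)
        stats = escore(net, "random", seed=1)  # continuous, ties a.s. absent
        ranked = normalize_scores(stats, "rank")
        perm = np.random.default_rng(6).permutation(net.n_nodes)
        mapped_edges = sorted(
            tuple(sorted((int(perm[u]), int(perm[v])))) for u, v in net.edges
        )
        net2 = Network([f"m{i}" for i in range(net.n_nodes)], mapped_edges)
        score_of = {
            tuple(sorted((int(perm[u]), int(perm[v])))): stats.scores[e]
            for e, (u, v) in enumerate(net.edges)
        }
        stats2 = EdgeStatistics(
            edges=list(net2.edges), model="t", network=net2,
            scores=np.array([score_of[e] for e in net2.edges]),
        )
        ranked2 = normalize_scores(stats2, "rank")
        for e2, edge2 in enumerate(net2.edges):
            e1 = next(
                e for e, (u, v) in enumerate(net.edges)
                if tuple(sorted((int(perm[u]), int(perm[v])))) == edge2
            )
            r1 = sorted(ranked.endpoint_scores[e1])
            r2 = sorted(ranked2.endpoint_scores[e2])
            assert r1 == r2


class TestFilter:
    def test_degree_quota_arithmetic(self):
        assert math.ceil(4**0.5) == 2

    def test_proportion_one_keeps_all(self):
        net = random_unweighted(15, 0.4, seed=7)
        stats = escore(net, "jaccard")
        keep = filter_edges(stats, "proportion", 1.0)
        assert len(keep) == net.n_edges

    def test_proportion_count(self):
        net = random_unweighted(15, 0.4, seed=8)
        stats = escore(net, "jaccard")
        keep = filter_edges(stats, "proportion", 0.3)
        assert len(keep) == int(math.floor(0.3 * net.n_edges))

    def test_threshold(self):
        net = random_unweighted(15, 0.4, seed=9)
        stats = escore(net, "jaccard")
        keep = filter_edges(stats, "threshold", 0.5)
        assert set(keep.tolist()) == set(np.nonzero(stats.scores >= 0.5)[0].tolist())

    def test_degree_filter_leaves_no_isolated_nodes(self):
        for seed in range(100):
            net = random_unweighted(20, 0.25, seed=seed)
            stats = normalize_scores(escore(net, "jaccard"), "rank")
            keep = filter_edges(stats, "degree", 0.5)
            covered = set()
            for e in keep:
                u, v = net.edges[e]
                covered |= {u, v}
            not_isolated = {u for edge in net.edges for u in edge}
            assert covered == not_isolated  # every rank-1 edge is nominated

    def test_parameter_range_checks(self):
        net = random_unweighted(10, 0.5, seed=10)
        stats = normalize_scores(escore(net, "jaccard"), "rank")
        with pytest.raises(ValueError):
            filter_edges(stats, "degree", 1.5)
        with pytest.raises(ValueError):
            filter_edges(stats, "proportion", -0.1)
        with pytest.raises(ValueError):
            filter_edges(stats, "bogus", 0.5)


class TestUmst:
    def _stats(self, net, scores):
        return EdgeStatistics(
            edges=list(net.edges), model="t", network=net, scores=np.asarray(scores, float)
        )

    def test_triangle_hand_case(self):
        net = Network(["a", "b", "c"], [(0, 1), (0, 2), (1, 2)])
        # a-b: 3, b-c: 2, a-c: 1
        scores = {(0, 1): 3.0, (1, 2): 2.0, (0, 2): 1.0}
        stats = self._stats(net, [scores[e] for e in net.edges])
        kept = umst(net, stats)
        assert {net.edges[e] for e in kept} == {(0, 1), (1, 2)}

    def test_all_equal_scores_keep_everything(self):
        net = complete_graph(4)
        stats = self._stats(net, [1.0] * net.n_edges)
        assert len(umst(net, stats)) == net.n_edges

    def test_spans_connected_graph(self):
        import networkx as nx

        for seed in range(20):
            net = random_unweighted(15, 0.35, seed=seed)
            G = nx.Graph(net.edges)
            G.add_nodes_from(range(net.n_nodes))
            if not nx.is_connected(G):
                continue
            rng = np.random.default_rng(seed)
            stats = self._stats(net, rng.random(net.n_edges))
            kept = umst(net, stats)
            H = nx.Graph(net.edges[e] for e in kept)
            H.add_nodes_from(range(net.n_nodes))
            assert nx.is_connected(H)

    def test_strictly_greater_characterization(self):
        # oracle: edge in UMST iff endpoints disconnected among strictly
        # greater edges
        import networkx as nx

        net = random_unweighted(12, 0.4, seed=30)
        rng = np.random.default_rng(31)
        scores = rng.integers(1, 5, net.n_edges).astype(float)  # force ties
        stats = self._stats(net, scores)
        kept = set(umst(net, stats).tolist())
        for e, (u, v) in enumerate(net.edges):
            H = nx.Graph(
                net.edges[e2] for e2 in range(net.n_edges) if scores[e2] > scores[e]
            )
            H.add_nodes_from([u, v])
            expected = not nx.has_path(H, u, v)
            assert (e in kept) == expected


class TestSimmelian:
    def test_bridge_between_cliques_zero(self):
        edges = []
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((i, j))
        for i in range(4, 8):
            for j in range(i + 1, 8):
                edges.append((i, j))
        edges.append((0, 4))
        net = Network([f"n{i}" for i in range(8)], sorted(edges))
        stats = simmelian_redundancy(net)
        bridge = net.edges.index((0, 4))
        assert stats.scores[bridge] == 0.0

    def test_k4_redundancy_one(self):
        stats = simmelian_redundancy(complete_graph(4))
        np.testing.assert_allclose(stats.scores, 1.0)

    def test_brute_force_oracle(self):
        net = random_unweighted(18, 0.3, seed=32)
        stats = simmelian_redundancy(net)
        nb = net.neighbor_sets()
        tri = {e: len(nb[u] & nb[v]) for e, (u, v) in zip(range(net.n_edges), net.edges)}
        strength = {edge: tri[e] for e, edge in enumerate(net.edges)}
        for e, (u, v) in enumerate(net.edges):
            def ranked(node, excl):
                lst = sorted(
                    (o for o in nb[node] if o != excl),
                    key=lambda o: (-strength[(min(node, o), max(node, o))], o),
                )
                return lst

            lu, lv = ranked(u, v), ranked(v, u)
            best = 0.0
            for size in range(1, max(len(lu), len(lv)) + 1):
                su, sv = set(lu[:size]), set(lv[:size])
                if su | sv:
                    best = max(best, len(su & sv) / len(su | sv))
            assert stats.scores[e] == pytest.approx(best)
            assert 0.0 <= stats.scores[e] <= 1.0


class TestPresets:
    def test_lspar_equals_custom_pipeline(self):
        for seed in range(100):
            net = random_unweighted(20, 0.3, seed=seed)
            preset = backbone_from_unweighted(net, model="lspar", parameter=0.5)
            custom = backbone_from_unweighted(
                net, parameter=0.5, escore_metric="jaccard",
                normalize="rank", filter="degree",
            )
            assert preset.backbone.edges == custom.backbone.edges

    def test_degree_preset_equals_custom_pipeline(self):
        for seed in range(100):
            net = random_unweighted(20, 0.3, seed=seed)
            preset = backbone_from_unweighted(net, model="degree", parameter=0.5)
            custom = backbone_from_unweighted(
                net, parameter=0.5, escore_metric="degree",
                normalize="rank", filter="degree",
            )
            assert preset.backbone.edges == custom.backbone.edges

    def test_backbone_subset_and_min_degree(self):
        net = random_unweighted(30, 0.3, seed=33)
        res = backbone_from_unweighted(net, model="lspar", parameter=0.5)
        assert set(res.backbone.edges) <= set(net.edges)
        deg = res.backbone.degrees()
        non_isolated = {u for edge in net.edges for u in edge}
        assert all(deg[u] >= 1 for u in non_isolated)

    def test_umst_flag_connects_backbone(self):
        import networkx as nx

        for seed in range(10):
            net = random_unweighted(20, 0.3, seed=seed)
            G = nx.Graph(net.edges)
            G.add_nodes_from(range(net.n_nodes))
            if not nx.is_connected(G):
                continue
            res = backbone_from_unweighted(
                net, parameter=0.2, escore_metric="jaccard",
                normalize="none", filter="proportion", umst_flag=True,
            )
            H = nx.Graph(res.backbone.edges)
            H.add_nodes_from(range(net.n_nodes))
            assert nx.is_connected(H)

    def test_skeleton_seeding_contract(self):
        net = random_unweighted(25, 0.4, seed=34)
        a = backbone_from_unweighted(net, model="skeleton", parameter=0.5, seed=3)
        b = backbone_from_unweighted(net, model="skeleton", parameter=0.5, seed=3)
        c = backbone_from_unweighted(net, model="skeleton", parameter=0.5, seed=4)
        assert a.backbone.edges == b.backbone.edges
        assert a.backbone.edges != c.backbone.edges

    def test_hyper_preset_uses_pvalue_threshold(self):
        net = random_unweighted(30, 0.4, seed=35)
        res = backbone_from_unweighted(net, model="hyper", parameter=0.05)
        stats = escore(net, "hyper")
        expected = {net.edges[e] for e in np.nonzero(stats.p_upper < 0.05)[0]}
        assert set(res.backbone.edges) == expected

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            backbone_from_unweighted(random_unweighted(10, 0.5, seed=0), model="spectral")

    def test_ba_degree_preset_preserves_hubs(self):
        hits = 0
        for seed in range(10):
            net = gen_preferential_attachment(n=60, m_per_step=3, seed=seed)
            res = backbone_from_unweighted(net, model="degree", parameter=0.5)
            k_in = net.degrees()
            k_bb = res.backbone.degrees()
            top_in = set(np.argsort(-k_in, kind="stable")[:5].tolist())
            fifth = np.sort(k_bb)[::-1][4]
            top_bb = set(np.nonzero(k_bb >= fifth)[0].tolist())
            hits += top_in <= top_bb
        assert hits >= 8

    def test_lspar_sbm_community_recovery_not_worse_than_dense(self):
        import networkx as nx
        from sklearn.metrics import adjusted_rand_score

        def ari(edges, labels):
            G = nx.Graph(edges)
            G.add_nodes_from(range(len(labels)))
            comms = nx.algorithms.community.greedy_modularity_communities(G)
            pred = np.zeros(len(labels), dtype=int)
            for ci, cset in enumerate(comms):
                for node in cset:
                    pred[node] = ci
            return adjusted_rand_score(labels, pred)

        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            net, labels = gen_sbm(seed=seed)
            res = backbone_from_unweighted(net, model="lspar", parameter=0.5)
            if ari(res.backbone.edges, labels) >= ari(net.edges, labels) - 1e-12:
                wins += 1
        assert wins >= int(0.8 * n_seeds)
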