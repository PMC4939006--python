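"""Centralities, communities, bridgeness and enrichment statistics."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chasnet import (
    betweenness,
    communities_greedy,
    communities_overlapping,
    date_party_scores,
    module_feature_enrichment,
    top_node_enrichment,
)
from chasnet.synthetic import GeneratorConfig, generate

from conftest import clique_edges, make_net


def brute_force_betweenness(net):
    """Count shortest paths through each node by explicit enumeration."""
    g = net.graph
    nodes = sorted(g.nodes)
    counts = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for mid in nodes:
            if mid in (s, t):
                continue
            through = sum(mid in p for p in paths)
            counts[mid] += through / len(paths)
    return pd.Series(counts)


class TestBetweenness:
    def test_path_middle_node(self):
        net = make_net([("a", "b"), ("b", "c")])
        bc = betweenness(net)
        assert bc["b"] == 1.0 and bc["a"] == 0.0 and bc["c"] == 0.0

    @pytest.mark.parametrize("k", range(3, 11))
    def test_star_center_closed_form(self, k):
        net = make_net([("c", f"l{i}") for i in range(k)])
        assert betweenness(net)["c"] == pytest.approx(k * (k - 1) / 2)

    def test_complete_graph_all_zero(self):
        net = make_net(clique_edges(range(5)))
        assert (betweenness(net) == 0).all()

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            n = int(rng.integers(5, 26))
            g = nx.gnm_random_graph(n, int(rng.integers(n, 3 * n)),
                                    seed=int(rng.integers(2**31)))
            net = make_net(list(g.edges), nodes=list(g.nodes))
            got = betweenness(net, lcc_only=False)
            expect = brute_force_betweenness(net)
            pd.testing.assert_series_equal(
                got.sort_index(), expect.sort_index(),
                check_names=False, atol=1e-9,
            )


class TestGreedyCommunities:
    def test_two_cliques_one_bridge(self):
        edges = clique_edges(["a1", "a2", "a3", "a4"]) + clique_edges(
            ["b1", "b2", "b3", "b4"]
        ) + [("a1", "b1")]
        comm = communities_greedy(make_net(edges))
        labels = comm.partition_labels()
        assert len(comm.modules) == 2
        assert len({labels[f"a{i}"] for i in range(1, 5)}) == 1
        assert labels["a1"] != labels["b1"]

    def test_single_clique_single_module(self):
        comm = communities_greedy(make_net(clique_edges(range(5))))
        assert len(comm.modules) == 1

    def test_partition_covers_every_node_once(self, small_dataset):
        comm = communities_greedy(small_dataset.network)
        sizes = sum(len(m) for m in comm.modules.values())
        assert sizes == small_dataset.network.n_nodes
        assert all(len(mods) == 1 for mods in comm.membership.values())

    def test_planted_partition_recovery(self, tmp_path):
        from sklearn.metrics import adjusted_rand_score

        cfg = GeneratorConfig(
            n_fragments=200, n_chromosomes=1, n_modules=4,
            within_module_edge_prob=0.3, between_module_edge_prob=0.01,
            features=(("f", 0.3, 0.3),), seed=7,
        )
        ds = generate(cfg, tmp_path)
        labels = communities_greedy(ds.network).partition_labels()
        truth = ds.truth_nodes.set_index("fragment_id")["module"]
        assert adjusted_rand_score(truth.loc[labels.index], labels) > 0.9


class TestOverlappingCommunities:
    def test_two_cliques_sharing_one_node(self):
        edges = clique_edges(["s", "a1", "a2", "a3", "a4"]) + clique_edges(
            ["s", "b1", "b2", "b3", "b4"]
        )
        comm = communities_overlapping(make_net(edges))
        br = comm.bridgeness_series()
        assert br["s"] == 2
        assert (br.drop("s") == 1).all()

    def test_disconnected_cliques_all_bridgeness_one(self):
        edges = clique_edges([1, 2, 3]) + clique_edges([4, 5, 6])
        br = communities_overlapping(make_net(edges)).bridgeness_series()
        assert (br == 1).all()

    def test_cover_includes_triangle_free_nodes(self):
        net = make_net(clique_edges([1, 2, 3]) + [(3, 4), (4, 5)])
        comm = communities_overlapping(net)
        assert set(comm.membership) == set(net.fragment_ids)
        assert comm.bridgeness_series().min() >= 1

    def test_planted_overlap_nodes_recovered(self, tmp_path):
        cfg = GeneratorConfig(
            n_fragments=60, n_chromosomes=1, n_modules=3,
            within_module_edge_prob=0.55, between_module_edge_prob=0.003,
            overlap_nodes=3, features=(("f", 0.3, 0.3),), seed=1,
        )
        ds = generate(cfg, tmp_path)
        br = communities_overlapping(ds.network).bridgeness_series()
        truth = set(
            ds.truth_nodes.loc[ds.truth_nodes.overlap_module >= 0, "fragment_id"]
        )
        predicted = set(br.index[br > 1])
        assert len(predicted ^ truth) <= 0.1 * ds.network.n_nodes


class TestTopNodeEnrichment:
    def test_constant_feature_enrichment_one(self):
        m = pd.DataFrame({"ones": np.ones(10)}, index=[f"n{i}" for i in range(10)])
        scores = pd.Series(np.arange(10), index=m.index, dtype=float)
        tab = top_node_enrichment(m, scores, top_n=3, n_reps=50, seed=0)
        assert tab["enrichment"].iloc[0] == pytest.approx(1.0)

    def test_concentrated_feature_ratio(self):
        # feature = 1 on the top-2 scored of 10 nodes: 1 / 0.2 = 5
        idx = [f"n{i}" for i in range(10)]
        scores = pd.Series(np.arange(10), index=idx, dtype=float)
        m = pd.DataFrame({"f": [0.0] * 8 + [1.0, 1.0]}, index=idx)
        tab = top_node_enrichment(m, scores, top_n=2, n_reps=200, seed=0)
        assert tab["enrichment"].iloc[0] == pytest.approx(5.0)
        assert tab["p"].iloc[0] <= 0.05

    def test_zero_global_mean_undefined(self):
        idx = [f"n{i}" for i in range(5)]
        m = pd.DataFrame({"zero": np.zeros(5)}, index=idx)
        scores = pd.Series(np.arange(5), index=idx, dtype=float)
        tab = top_node_enrichment(m, scores, top_n=2, n_reps=10, seed=0)
        assert np.isnan(tab["enrichment"].iloc[0])

    def test_independent_feature_calibration(self):
        """p is uniform for a feature unrelated to the scores (~5 % at 0.05)."""
        rng = np.random.default_rng(12)
        idx = [f"n{i}" for i in range(100)]
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            m = pd.DataFrame({"f": rng.random(100)}, index=idx)
            scores = pd.Series(rng.random(100), index=idx)
            tab = top_node_enrichment(m, scores, top_n=20, n_reps=99,
                                      seed=int(rng.integers(2**31)))
            if tab["p"].iloc[0] <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.10

    def test_top_n_larger_than_universe_rejected(self):
        m = pd.DataFrame({"f": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            top_node_enrichment(m, pd.Series({"a": 1.0}), top_n=2)


class TestDatePartyScores:
    def _table(self, feats, enr):
        return pd.DataFrame({"feature": feats, "enrichment": enr})

    def test_quadrant_labels(self):
        feats = ["party_like", "date_like", "neutral_like", "nan_like"]
        bridge = self._table(feats, [0.4, 2.0, 1.0, np.nan])
        betw = self._table(feats, [2.5, 1.5, 1.0, 1.0])
        out = date_party_scores(bridge, betw).set_index("feature")
        assert out.loc["party_like", "label"] == "party"
        assert out.loc["date_like", "label"] == "date"
        assert out.loc["neutral_like", "label"] == "neutral"
        assert out.loc["nan_like", "label"] == "undefined"

    def test_mismatched_features_rejected(self):
        with pytest.raises(ValueError):
            date_party_scores(
                self._table(["a"], [1.0]), self._table(["b"], [1.0])
            )


class TestModuleFeatureEnrichment:
    def test_concentrated_feature_hits_minimum_p(self):
        edges = clique_edges(["a1", "a2", "a3", "a4"]) + clique_edges(
            ["b1", "b2", "b3", "b4"]
        ) + [("a1", "b1")]
        net = make_net(edges)
        comm = communities_greedy(net)
        m = pd.DataFrame(
            {"f": [1.0 if n.startswith("a") else 0.0 for n in net.fragment_ids]},
            index=net.fragment_ids,
        )
        p = module_feature_enrichment(comm, m, n_reps=200, seed=0)
        assert p["f"].min() == pytest.approx(1 / 201)
        labels = comm.partition_labels()
        hot = labels["a1"]
        assert p.loc[hot, "f"] == pytest.approx(1 / 201)

    def test_uniform_feature_not_enriched(self):
        net = make_net(clique_edges([1, 2, 3]) + clique_edges([4, 5, 6]))
        comm = communities_greedy(net)
        m = pd.DataFrame({"f": np.ones(6)}, index=net.fragment_ids)
        p = module_feature_enrichment(comm, m, n_reps=100, seed=0)
        assert (p["f"] > 0.5).all()

    def test_planted_module_signal(self, tmp_path):
        """Feature planted in specific modules is significant exactly there."""
        cfg = GeneratorConfig(
            n_fragments=120, n_chromosomes=1, n_modules=4,
            within_module_edge_prob=0.4, between_module_edge_prob=0.01,
            features=(("f", 0.3, 0.3),), seed=3,
        )
        ds = generate(cfg, tmp_path)
        comm = communities_greedy(ds.network)
        truth = ds.truth_nodes.set_index("fragment_id")
        # plant: value 1 on planted modules 0 and 1, else 0
        vals = (truth["module"] < 2).astype(float)
        m = pd.DataFrame({"planted": vals.loc[ds.network.fragment_ids]})
        p = module_feature_enrichment(comm, m, n_reps=1000, seed=0)
        labels = comm.partition_labels()
        hot_modules = {
            labels[n] for n in labels.index if truth.loc[n, "module"] < 2
        }
        for mod in p.index:
            if mod in hot_modules:
                assert p.loc[mod, "planted"] <= 0.01
            else:
                assert p.loc[mod, "planted"] > 0.01
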