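"""Greedy active-subnetwork search: scoring, expansion, rounds, iteration."""

import math

import networkx as nx
import numpy as np
import pytest

from diagnet.network import induce_subnetwork
from diagnet.scoring import score_genes, select_diagnostic_genes
from diagnet.search import (
    SearchConfig,
    greedy_expand,
    iterate_search,
    module_score,
    search_round,
)
from diagnet.synthetic import SimConfig, generate_expression, generate_network

from oracles import connected_subgraph_optimum, random_connected_graph


def _star(n_leaves, center_t=5.0, leaf_t=4.0):
    net = nx.Graph()
    scores = {"C": center_t}
    for i in range(n_leaves):
        leaf = f"L{i}"
        net.add_edge("C", leaf)
        scores[leaf] = leaf_t
    return net, scores


class TestModuleScore:
    def test_single_node(self):
        assert module_score(["A"], {"A": 3.0}, "sum") == 3.0
        assert module_score(["A"], {"A": 3.0}, "norm_agg") == 3.0

    def test_norm_agg_formula(self):
        scores = {"A": 3.0, "B": -3.0, "C": 3.0}
        assert module_score(scores, scores, "norm_agg") == pytest.approx(
            9 / math.sqrt(3)
        )

    def test_size_penalty(self):
        scores = {"A": 3.0, "B": 3.0, "Z": 0.0}
        with_z = module_score(["A", "B", "Z"], scores, "norm_agg")
        without = module_score(["A", "B"], scores, "norm_agg")
        assert with_z < without

    def test_missing_score_errors(self):
        with pytest.raises(KeyError):
            module_score(["A"], {}, "sum")

    def test_mi_method_runs_and_is_bounded(self):
        net, scores = _star(6)
        val = module_score(["C"], scores, "mi", net=net)
        assert np.isfinite(val) and val >= 0


class TestGreedyExpand:
    def test_isolated_seed(self):
        net = nx.Graph()
        net.add_node("A")
        mod = greedy_expand(net, {"A": 2.0}, "A")
        assert mod.nodes == frozenset({"A"})
        assert mod.score == 2.0

    def test_path_stops_at_seed(self):
        # a(3) - b(0.1) - c(3): adding b drops the normalized score
        net = nx.Graph([("a", "b"), ("b", "c")])
        scores = {"a": 3.0, "b": 0.1, "c": 3.0}
        mod = greedy_expand(net, scores, "a", SearchConfig(method="norm_agg"))
        assert mod.nodes == frozenset({"a"})
        assert mod.score == pytest.approx(3.0)

    def test_star_sum_takes_everything(self):
        net, scores = _star(6)
        mod = greedy_expand(net, scores, "C", SearchConfig(method="sum"))
        assert mod.nodes == frozenset(net.nodes())
        assert mod.score == pytest.approx(5 + 4 * 6)

    def test_score_equals_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            adjacency, t = random_connected_graph(10, 0.25, rng)
            net = nx.Graph()
            net.add_nodes_from(range(10))
            for i, nbrs in enumerate(adjacency):
                net.add_edges_from((i, j) for j in nbrs)
            scores = dict(enumerate(t))
            mod = greedy_expand(net, scores, 0, SearchConfig())
            assert mod.score == pytest.approx(
                module_score(mod.nodes, scores, "norm_agg"), abs=1e-12
            )

    def test_connected_result(self, small_instance):
        network, truth, datasets = small_instance
        table = score_genes(datasets[0], datasets[0].genes)
        scores = table["t"].dropna().to_dict()
        seed = sorted(truth.planted_module)[0]
        mod = greedy_expand(network, scores, seed)
        assert nx.is_connected(network.subgraph(mod.nodes))

    def test_unknown_seed_errors(self):
        with pytest.raises(KeyError):
            greedy_expand(nx.Graph([("A", "B")]), {"A": 1, "B": 1}, "Z")


class TestGreedyOracleBound:
    def test_star_and_path_equal_optimum(self):
        net, scores = _star(4)
        mod = greedy_expand(net, scores, "C", SearchConfig(method="sum"))
        nodes = sorted(net.nodes())
        idx = {n: i for i, n in enumerate(nodes)}
        adjacency = [set(idx[m] for m in net.neighbors(n)) for n in nodes]
        best = connected_subgraph_optimum(
            adjacency, [abs(scores[n]) for n in nodes], idx["C"], "sum"
        )
        assert mod.score == pytest.approx(best)

        net = nx.path_graph(3)
        scores = {0: 3.0, 1: 0.1, 2: 3.0}
        mod = greedy_expand(net, scores, 0, SearchConfig(method="norm_agg"))
        best = connected_subgraph_optimum(
            [{1}, {0, 2}, {1}], [3.0, 0.1, 3.0], 0, "norm_agg"
        )
        assert mod.score <= best + 1e-12
        assert mod.score == pytest.approx(3.0)

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            adjacency, t = random_connected_graph(n, 0.3, rng)
            net = nx.Graph()
            net.add_nodes_from(range(n))
            for i, nbrs in enumerate(adjacency):
                net.add_edges_from((i, j) for j in nbrs)
            seed = int(rng.integers(n))
            scores = dict(enumerate(t))
            mod = greedy_expand(net, scores, seed, SearchConfig())
            best = connected_subgraph_optimum(adjacency, list(t), seed, "norm_agg")
            assert mod.score <= best + 1e-9


class TestSearchRound:
    def test_topk_all_equals_full_union(self):
        net = nx.path_graph(6)
        scores = {i: float(i + 1) for i in net.nodes()}
        cfg_all = SearchConfig(top_k=6)
        union_all = search_round(net, scores, cfg_all)
        expected = set()
        for seed in net.nodes():
            expected |= greedy_expand(net, scores, seed, cfg_all).nodes
        assert union_all == expected

    def test_deterministic(self, small_instance):
        network, _, datasets = small_instance
        table = score_genes(datasets[0], datasets[0].genes)
        scores = table["t"].dropna().to_dict()
        assert search_round(network, scores) == search_round(network, scores)

    def test_union_contains_planted_module(self, default_instance):
        _, network, truth, datasets = default_instance
        table = score_genes(datasets[0], datasets[0].genes)
        union = search_round(network, table["t"].dropna().to_dict())
        frac = len(union & truth.planted_module) / len(truth.planted_module)
        assert frac >= 0.9


class TestIterateSearch:
    def test_small_input_returned_unchanged(self):
        net = nx.path_graph(5)
        scores = {i: 1.0 for i in net.nodes()}
        res = iterate_search(net, scores, SearchConfig(stop_size=50))
        assert res.nodes == frozenset(net.nodes())
        assert res.rounds.empty

    def test_round_sizes_non_increasing(self, default_instance):
        _, network, _, datasets = default_instance
        table = score_genes(datasets[0], datasets[0].genes)
        res = iterate_search(network, table["t"].dropna().to_dict())
        sizes = res.rounds["n_nodes"].to_numpy()
        assert np.all(np.diff(sizes) <= 0)

    def test_idempotent_on_own_output(self, default_instance):
        _, network, _, datasets = default_instance
        table = score_genes(datasets[0], datasets[0].genes)
        scores = table["t"].dropna().to_dict()
        res = iterate_search(network, scores)
        again = iterate_search(res.graph, scores)
        assert again.nodes == res.nodes

    def test_pipeline_flow_recovers_planted_module(self):
        jacs = []
        for seed in range(5):
            cfg = SimConfig(rng_seed=seed)
            net, truth = generate_network(cfg)
            ds = generate_expression(net, truth, cfg)[0]
            table = score_genes(ds, ds.genes)
            sub = induce_subnetwork(net, select_diagnostic_genes(table))
            res = iterate_search(sub, table["t"].dropna().to_dict())
            jacs.append(
                len(res.nodes & truth.planted_module)
                / len(res.nodes | truth.planted_module)
            )
        assert np.median(jacs) >= 0.7

    def test_monotone_signal_response(self):
        # stronger planted effects never reduce median recovery
        medians = []
        for effect in (0.0, 1.0, 2.0):
            jacs = []
            for seed in range(8):
                cfg = SimConfig(
                    n_genes=150,
                    module_size=15,
                    n_cohorts=1,
                    effect_size=effect,
                    rng_seed=seed,
                )
                net, truth = generate_network(cfg)
                ds = generate_expression(net, truth, cfg)[0]
                table = score_genes(ds, ds.genes)
                sub = induce_subnetwork(net, select_diagnostic_genes(table))
                if sub.number_of_nodes() == 0:
                    jacs.append(0.0)
                    continue
                res = iterate_search(sub, table["t"].dropna().to_dict())
                jacs.append(
                    len(res.nodes & truth.planted_module)
                    / len(res.nodes | truth.planted_module)
                )
            medians.append(np.median(jacs))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9
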