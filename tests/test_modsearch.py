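import networkx as nx
import numpy as np
import pandas as pd
import pytest

from activemod.modsearch import (
    GAConfig,
    assign_weights,
    best_component,
    extract_seeded_module,
    jaccard,
    score_subnetwork,
    search_exhaustive,
    search_ga,
)
from activemod.synthio import PlantedModuleTruth, gen_ppi_with_planted_module


def path_graph(weights):
    g = nx.path_graph(list(weights))
    return g, dict(weights)


class TestAssignWeights:
    @pytest.mark.parametrize("p, w", [(0.01, 2.0), (1.0, 0.0), (0.0, 300.0)])
    def test_log_transform_and_cap(self, p, w):
        de = pd.DataFrame({"p": [p]}, index=["g"])
        assert assign_weights(de)["g"] == pytest.approx(w)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            assign_weights(pd.DataFrame({"p": []}))


class TestScoreSubnetwork:
    def test_single_node(self):
        g = nx.Graph()
        g.add_node("A")
        assert score_subnetwork({"A"}, g, {"A": 3.0}, 1.0) == pytest.approx(2.0)

    def test_disconnected_nodes_take_best_component_not_sum(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        assert score_subnetwork({"A", "B"}, g, {"A": 3.0, "B": 3.0}, 1.0) == pytest.approx(2.0)

    def test_empty_set_scores_zero(self):
        g, w = path_graph({"A": 1.0, "B": 2.0})
        assert score_subnetwork(set(), g, w, 1.0) == 0.0

    def test_unknown_node_errors(self):
        g, w = path_graph({"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError, match="unknown"):
            score_subnetwork({"Z"}, g, w, 1.0)

    def test_matches_component_enumeration_oracle(self):
        """Oracle: enumerate components with networkx and sum weights."""
        rng = np.random.default_rng(7)
        g = nx.gnm_random_graph(14, 20, seed=1)
        w = {n: float(rng.uniform(0, 4)) for n in g}
        lam = 1.0
        for _ in range(20):
            size = int(rng.integers(1, 9))
            nodes = set(rng.choice(14, size=size, replace=False).tolist())
            expect = max(
                sum(w[n] - lam for n in comp)
                for comp in nx.connected_components(g.subgraph(nodes))
            )
            assert score_subnetwork(nodes, g, w, lam) == pytest.approx(expect)

    def test_zero_penalty_positive_weights_maximized_by_full_component(self):
        rng = np.random.default_rng(8)
        g = nx.gnm_random_graph(10, 14, seed=2)
        w = {n: float(rng.uniform(0.1, 2)) for n in g}
        opt = search_exhaustive(g, w, 0.0)
        comp_scores = [
            sum(w[n] for n in comp) for comp in nx.connected_components(g)
        ]
        assert opt.score == pytest.approx(max(comp_scores))


class TestSearchExhaustive:
    def test_bridging_through_weak_node_pays(self):
        g, w = path_graph({"A": 3.0, "B": 0.1, "C": 3.0})
        res = search_exhaustive(g, w, 1.0)
        assert res.nodes == {"A", "B", "C"}
        # hand enumeration of all 6 connected subsets: (3-1)+(0.1-1)+(3-1)
        assert res.score == pytest.approx(3.1)

    def test_weak_tail_is_left_out(self):
        g, w = path_graph({"A": 3.0, "B": 0.1, "C": 0.2})
        res = search_exhaustive(g, w, 1.0)
        assert res.nodes == {"A"}
        assert res.score == pytest.approx(2.0)

    def test_all_zero_weights_tie_break_to_empty(self):
        g, w = path_graph({"A": 0.0, "B": 0.0, "C": 0.0})
        res = search_exhaustive(g, w, 0.0)
        assert res.nodes == frozenset()
        assert res.score == 0.0

    def test_guard_refuses_large_graphs(self):
        g = nx.path_graph(19)
        with pytest.raises(ValueError, match="too large"):
            search_exhaustive(g, {n: 1.0 for n in g}, 0.0)


class TestSearchGA:
    def test_nothing_profitable_returns_empty_module(self):
        g, w = path_graph({"A": 0.5, "B": 0.2, "C": 0.9})
        res = search_ga(g, w, GAConfig(population_size=20, generations=20,
                                       lambda_penalty=1.0, seed=0))
        assert res.nodes == frozenset()
        assert res.score == 0.0

    def test_reproducible_under_fixed_seed(self):
        truth = PlantedModuleTruth(module_nodes=frozenset(range(6)), seed=3)
        g, pvals = gen_ppi_with_planted_module(60, 4.0, truth)
        w = {n: -np.log10(p) for n, p in pvals.items()}
        cfg = GAConfig(population_size=40, generations=40, seed=5)
        a = search_ga(g, w, cfg)
        b = search_ga(g, w, cfg)
        assert a.nodes == b.nodes
        assert a.score == b.score
        assert a.provenance == b.provenance

    def test_never_beats_exhaustive_and_usually_matches(self):
        rng = np.random.default_rng(9)
        wins = 0
        for i in range(12):
            g = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(2**31)))
            w = {n: float(rng.uniform(0, 3)) for n in g}
            opt = search_exhaustive(g, w, 1.0)
            ga = search_ga(g, w, GAConfig(population_size=60, generations=60,
                                          lambda_penalty=1.0,
                                          seed=int(rng.integers(2**31))))
            assert ga.score <= opt.score + 1e-9
            wins += abs(ga.score - opt.score) < 1e-9
        assert wins >= 10

    def test_score_certificate_is_consistent(self):
        truth = PlantedModuleTruth(module_nodes=frozenset(range(5)), seed=4)
        g, pvals = gen_ppi_with_planted_module(40, 4.0, truth)
        w = {n: -np.log10(p) for n, p in pvals.items()}
        res = search_ga(g, w, GAConfig(population_size=30, generations=30, seed=2))
        assert res.connected
        assert res.score == pytest.approx(
            score_subnetwork(res.nodes, g, w, GAConfig().lambda_penalty)
        )

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            search_ga(nx.Graph(), {}, GAConfig())


class TestMonotonicity:
    def test_profitable_adjacent_node_never_lowers_optimum(self):
        rng = np.random.default_rng(10)
        for i in range(5):
            g = nx.gnp_random_graph(9, 0.4, seed=i)
            w = {n: float(rng.uniform(0, 2.5)) for n in g}
            base = search_exhaustive(g, w, 1.0).score
            g2 = g.copy()
            new = "extra"
            anchor = int(rng.integers(9))
            g2.add_edge(anchor, new)
            w2 = {**w, new: 1.0 + float(rng.uniform(0.1, 2.0))}
            assert search_exhaustive(g2, w2, 1.0).score >= base - 1e-12


class TestRecoveryDegradation:
    def test_jaccard_decreases_with_module_weight(self):
        """Recovery should degrade gracefully as the planted module's
        weight separation from background shrinks."""
        means = {}
        for mu in (3.0, 1.5, 0.8):
            js = []
            for seed in range(1, 11):
                truth = PlantedModuleTruth(
                    module_nodes=frozenset(range(10)),
                    module_weight_dist=(mu, 0.5),
                    background_weight_dist=(0.5, 0.3),
                    seed=20 + seed,
                )
                g, pvals = gen_ppi_with_planted_module(120, 4.0, truth)
                w = {n: -np.log10(p) for n, p in pvals.items()}
                res = search_ga(g, w, GAConfig(population_size=100, generations=100,
                                               lambda_penalty=1.0, seed=seed))
                js.append(jaccard(res.nodes, truth.module_nodes))
            means[mu] = np.mean(js)
        assert means[3.0] >= means[1.5] >= means[0.8]


class TestExtractSeededModule:
    def make_result(self, g, w, lam=1.0):
        return search_exhaustive(g, w, lam)

    def test_radius_zero_is_seed_intersection(self, wnt_motif_graph):
        from activemod.modsearch import ModuleResult

        res = ModuleResult(frozenset(wnt_motif_graph.nodes), 1.0, True, {})
        out = extract_seeded_module(res, wnt_motif_graph, {"RACGAP1"}, radius=0)
        assert out.nodes == {"RACGAP1"}

    def test_wnt_motif_radius_two_recovers_all(self, wnt_motif_graph):
        from activemod.modsearch import ModuleResult

        res = ModuleResult(frozenset(wnt_motif_graph.nodes), 1.0, True, {})
        out = extract_seeded_module(res, wnt_motif_graph, {"RACGAP1"}, radius=2)
        assert out.nodes == {
            "RACGAP1", "AURKA", "CCNB1", "PLK1", "CTNNB1", "CDKN1A"
        }
        assert out.connected

    def test_radius_beyond_diameter_returns_whole_module(self, wnt_motif_graph):
        from activemod.modsearch import ModuleResult

        res = ModuleResult(frozenset(wnt_motif_graph.nodes), 1.0, True, {})
        out = extract_seeded_module(res, wnt_motif_graph, {"RACGAP1"}, radius=10)
        assert out.nodes == set(wnt_motif_graph.nodes)

    def test_seed_outside_module_errors(self, wnt_motif_graph):
        from activemod.modsearch import ModuleResult

        res = ModuleResult(frozenset({"AURKA", "RACGAP1"}), 1.0, True, {})
        with pytest.raises(ValueError, match="seed"):
            extract_seeded_module(res, wnt_motif_graph, {"CDKN1A"})


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(set(), set(), 1.0), ({1}, set(), 0.0), ({1, 2}, {2, 3}, 1 / 3)],
    )
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)
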