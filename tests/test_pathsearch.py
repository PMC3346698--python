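import itertools
import math

import networkx as nx
import numpy as np
import pytest

from pathcolor.coloring import uniform_coloring
from pathcolor.netbuild import WEIGHT_KEY
from pathcolor.pathsearch import (
    PathResult,
    PathStats,
    SearchConfig,
    assemble_network,
    astar_colorful_path,
    bound_score,
    colorful_path_exists,
    location_monotone,
    sample_path_stats,
    search_with_restarts,
)
from pathcolor.synthetic import planted_instance

from conftest import random_weighted_graph, weighted_graph


def brute_force_best(net, coloring, s, t, l, locations=None):
    """Exhaustive minimum over colorful, location-valid simple l-node s-t paths."""
    best = None

    def dfs(v, path, g):
        nonlocal best
        if len(path) == l:
            if (
                v == t
                and len({coloring.color[u] for u in path}) == l
                and location_monotone(path, locations)
            ):
                cand = (g, tuple(path))
                if best is None or cand < best:
                    best = cand
            return
        for u in sorted(net[v]):
            if u not in path:
                dfs(u, path + [u], g + net[v][u][WEIGHT_KEY])

    dfs(s, [s], 0.0)
    return best


class TestSamplePathStats:
    def test_uniform_weights_degenerate(self, path_graph):
        stats = sample_path_stats(path_graph, 3, n_samples=50, seed=0)
        assert stats.w_avg == pytest.approx(1.0)
        assert stats.w_std == pytest.approx(0.0)
        assert stats.w_min == pytest.approx(1.0)

    def test_matches_enumeration_on_complete_graph(self):
        # on K6 a self-avoiding walk is uniform over simple l-node paths, so
        # the pooled per-edge mean must match exhaustive enumeration
        rng = np.random.default_rng(10)
        net = nx.complete_graph([f"N{i}" for i in range(6)])
        for u, v in net.edges():
            net[u][v][WEIGHT_KEY] = float(rng.uniform(0.2, 3.0))
        l = 4
        pooled = []
        for perm in itertools.permutations(sorted(net.nodes()), l):
            pooled.extend(net[a][b][WEIGHT_KEY] for a, b in zip(perm, perm[1:]))
        expected = float(np.mean(pooled))
        stats = sample_path_stats(net, l, n_samples=5000, seed=1)
        se = float(np.std(pooled)) / math.sqrt(stats.n_samples * (l - 1))
        assert abs(stats.w_avg - expected) < 4 * se

    def test_deterministic_under_seed(self, path_graph):
        a = sample_path_stats(path_graph, 4, n_samples=200, seed=3)
        b = sample_path_stats(path_graph, 4, n_samples=200, seed=3)
        assert (a.w_avg, a.w_std, a.w_min) == (b.w_avg, b.w_std, b.w_min)

    def test_impossible_length_errors(self, triangle_graph):
        with pytest.raises(RuntimeError):
            sample_path_stats(triangle_graph, 4, n_samples=5, seed=0)

    def test_zero_samples_rejected(self, path_graph):
        with pytest.raises(ValueError):
            sample_path_stats(path_graph, 3, n_samples=0)


class TestBoundScore:
    def test_printed_arithmetic(self):
        stats = PathStats(w_min=0.1, w_avg=1.7, w_std=0.2, n_samples=100, l=7)
        assert bound_score(stats, 0.5, 7) == pytest.approx(12.6)

    def test_alpha_zero(self):
        stats = PathStats(w_min=0.1, w_avg=1.7, w_std=0.2, n_samples=100, l=7)
        assert bound_score(stats, 0.0, 7) == pytest.approx(1.7 * 7)

    def test_strictly_increasing_in_alpha(self):
        stats = PathStats(w_min=0.1, w_avg=1.0, w_std=0.5, n_samples=10, l=5)
        values = [bound_score(stats, a, 5) for a in (0.0, 0.5, 1.0, 2.0)]
        assert values == sorted(values) and len(set(values)) == len(values)

    def test_edge_count_mode(self):
        stats = PathStats(w_min=0.1, w_avg=2.0, w_std=0.0, n_samples=10, l=5)
        assert bound_score(stats, 0.0, 5, edge_count=True) == pytest.approx(8.0)


class TestAstar:
    def test_unique_path_on_path_graph(self, path_graph):
        col = uniform_coloring(path_graph, 5, seed=0)
        col.color.update({v: i + 1 for i, v in enumerate("ABCDE")})
        cfg = SearchConfig(l=5, d=1)
        res = astar_colorful_path(path_graph, col, "A", "E", cfg)
        assert res is not None
        assert res.nodes == ("A", "B", "C", "D", "E")
        assert res.weight == pytest.approx(4.0)

    def test_matches_brute_force_with_infinite_bound(self):
        rng = np.random.default_rng(11)
        n_nonempty = 0
        for _ in range(30):
            net = random_weighted_graph(rng, p=0.5)
            nodes = sorted(net.nodes())
            s, t = nodes[0], nodes[-1]
            l = int(rng.integers(3, 6))
            col = uniform_coloring(net, l, seed=int(rng.integers(2**31)))
            locs = {
                v: (int(rng.integers(1, 4)) if rng.random() < 0.5 else None)
                for v in nodes
            }
            cfg = SearchConfig(l=l, d=1)
            oracle = brute_force_best(net, col, s, t, l, locs)
            got = astar_colorful_path(net, col, s, t, cfg, math.inf, locs, debug=True)
            if oracle is None:
                assert got is None
            else:
                n_nonempty += 1
                assert got.weight == pytest.approx(oracle[0])
                assert got.nodes == oracle[1]
        assert n_nonempty >= 3

    def test_bound_below_optimum_returns_none(self, path_graph):
        col = uniform_coloring(path_graph, 5, seed=0)
        col.color.update({v: i + 1 for i, v in enumerate("ABCDE")})
        cfg = SearchConfig(l=5, d=2)
        res = astar_colorful_path(path_graph, col, "A", "E", cfg, bound=3.5)
        assert res is None

    def test_bound_at_optimum_returns_optimum(self, path_graph):
        col = uniform_coloring(path_graph, 5, seed=0)
        col.color.update({v: i + 1 for i, v in enumerate("ABCDE")})
        cfg = SearchConfig(l=5, d=2)
        res = astar_colorful_path(path_graph, col, "A", "E", cfg, bound=4.0)
        assert res is not None and res.weight == pytest.approx(4.0)

    def test_admissible_heuristic_on_small_graphs(self):
        # w_min * (remaining steps) never exceeds the cheapest completion
        rng = np.random.default_rng(12)
        for _ in range(10):
            net = random_weighted_graph(rng, n_max=8, p=0.6)
            w_min = min(d[WEIGHT_KEY] for *_, d in net.edges(data=True))
            nodes = sorted(net.nodes())
            l = 4
            for perm in itertools.permutations(nodes, 2):
                s, t = perm
                best = brute_force_best(
                    net, uniform_coloring(net, l, seed=0), s, t, l
                )
                # compare against unconstrained completions from every prefix
                if best is None:
                    continue
                g_total, path = best
                for d in range(1, l):
                    g_prefix = sum(
                        net[a][b][WEIGHT_KEY] for a, b in zip(path[:d], path[1:d])
                    )
                    assert g_prefix + w_min * (l - d) <= g_total + 1e-9
                break

    def test_location_constraint_filters_paths(self):
        net = weighted_graph(
            [("s", "a", 1), ("a", "t", 1), ("s", "b", 5), ("b", "t", 5)]
        )
        col = uniform_coloring(net, 3, seed=0)
        col.color.update({"s": 1, "a": 2, "b": 2, "t": 3})
        locs = {"s": 1, "a": 3, "b": 2, "t": 2}  # via a: rank drops 3 -> 2
        cfg = SearchConfig(l=3, d=1, enforce_location=True)
        res = astar_colorful_path(net, col, "s", "t", cfg, locations=locs)
        assert res is not None and res.nodes == ("s", "b", "t")
        cfg_free = SearchConfig(l=3, d=1, enforce_location=False)
        res_free = astar_colorful_path(net, col, "s", "t", cfg_free, locations=locs)
        assert res_free.nodes == ("s", "a", "t")
        assert not res_free.location_valid

    def test_missing_endpoint_errors(self, path_graph):
        col = uniform_coloring(path_graph, 4, seed=0)
        with pytest.raises(KeyError):
            astar_colorful_path(path_graph, col, "A", "Z", SearchConfig(l=4, d=1))


class TestExistenceSearch:
    def test_agrees_with_astar(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            net = random_weighted_graph(rng, p=0.5)
            nodes = sorted(net.nodes())
            s, t = nodes[0], nodes[-1]
            l = int(rng.integers(3, 6))
            col = uniform_coloring(net, l, seed=int(rng.integers(2**31)))
            cfg = SearchConfig(l=l, d=1)
            found = astar_colorful_path(net, col, s, t, cfg) is not None
            assert colorful_path_exists(net, col, s, t, l) == found


class TestSearchWithRestarts:
    def test_recovers_planted_path(self):
        inst = planted_instance(n=40, l=5, seed=21)
        cfg = SearchConfig(l=5, d=2, alpha=0.5)
        res = search_with_restarts(
            inst.net, inst.planted[0], inst.planted[-1], cfg,
            n_colorings=200, seed=2, locations=inst.locations, stats_samples=500,
        )
        assert res and list(res[0].nodes) == inst.planted

    def test_deterministic_under_master_seed(self):
        inst = planted_instance(n=30, l=4, seed=22)
        cfg = SearchConfig(l=4, d=2)
        kwargs = dict(n_colorings=50, seed=5, locations=inst.locations, stats_samples=300)
        a = search_with_restarts(inst.net, inst.planted[0], inst.planted[-1], cfg, **kwargs)
        b = search_with_restarts(inst.net, inst.planted[0], inst.planted[-1], cfg, **kwargs)
        assert [(r.nodes, r.weight) for r in a] == [(r.nodes, r.weight) for r in b]

    def test_results_sorted_and_deduplicated(self):
        inst = planted_instance(n=30, l=4, seed=23)
        cfg = SearchConfig(l=4, d=2, max_results=5)
        res = search_with_restarts(
            inst.net, inst.planted[0], inst.planted[-1], cfg,
            n_colorings=100, seed=1, stats_samples=300,
        )
        weights = [r.weight for r in res]
        assert weights == sorted(weights)
        assert len({r.nodes for r in res}) == len(res)
        assert len(res) <= 5


class TestAssembleNetwork:
    def test_half_chain_retention(self):
        chain = [f"M{i}" for i in range(11)]
        p1 = PathResult(tuple(chain[:6] + ["X"]), 1.0)  # hits 6 of 11
        p2 = PathResult(("M0", "M1", "Y", "Z"), 1.0)  # hits 2 of 11
        out = assemble_network([p1, p2], chain)
        assert set(out.nodes()) == set(p1.nodes)

    def test_empty_path_list(self):
        assert assemble_network([], ["A", "B"]).number_of_nodes() == 0

    def test_union_oracle(self):
        chain = ["A", "B", "C", "D"]
        paths = [
            PathResult(("A", "B", "X"), 1.0),
            PathResult(("C", "D", "Y"), 2.0),
            PathResult(("P", "Q", "R"), 3.0),
        ]
        out = assemble_network(paths, chain)
        kept = [p for p in paths if len(set(p.nodes) & set(chain)) >= 2]
        exp_nodes = set().union(*(p.nodes for p in kept))
        exp_edges = {frozenset(e) for p in kept for e in zip(p.nodes, p.nodes[1:])}
        assert set(out.nodes()) == exp_nodes
        assert {frozenset(e) for e in out.edges()} == exp_edges

    def test_output_subgraph_of_input_paths(self):
        inst = planted_instance(n=30, l=4, seed=24)
        paths = [PathResult(tuple(inst.planted), 0.5)]
        out = assemble_network(paths, inst.planted)
        assert set(out.nodes()) <= set(inst.net.nodes())
        assert all(inst.net.has_edge(u, v) for u, v in out.edges())

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            assemble_network([], [])
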