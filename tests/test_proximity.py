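"""Shortest-path distributions, per-drug proximity, threshold sets, ego graphs."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dsgn.proximity import (
    background_distances,
    cross_set_distance_per_drug,
    drugs_below_threshold,
    ego_subgraph,
    shortest_paths_from,
    within_set_distances,
)
from dsgn.synthetic import gen_ppi, module_map


def floyd_warshall_oracle(g):
    """Dense hop-count all-pairs distances; inf where unreachable."""
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0)
    for u, v in g.edges:
        D[idx[u], idx[v]] = D[idx[v], idx[u]] = 1
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    return nodes, D


class TestShortestPathsFrom:
    def test_path_graph(self, path_graph):
        assert shortest_paths_from(path_graph, "a") == {"a": 0, "b": 1, "c": 2}

    def test_unreachable_absent(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_edge("x", "y")
        d = shortest_paths_from(g, "a")
        assert "x" not in d and "y" not in d

    def test_unknown_source(self, path_graph):
        with pytest.raises(KeyError):
            shortest_paths_from(path_graph, "zz")

    def test_erdos_renyi_vs_floyd_warshall(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            g = nx.gnp_random_graph(40, 0.08, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            nodes, D = floyd_warshall_oracle(g)
            idx = {n: i for i, n in enumerate(nodes)}
            for src in nodes[:10]:
                d = shortest_paths_from(g, src)
                for tgt in nodes:
                    if np.isfinite(D[idx[src], idx[tgt]]):
                        assert d[tgt] == int(D[idx[src], idx[tgt]])
                    else:
                        assert tgt not in d

    def test_symmetry_and_triangle_inequality(self):
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        nodes = sorted(g.nodes)
        dist = {u: shortest_paths_from(g, u) for u in nodes}
        for u, v in itertools.combinations(nodes, 2):
            if v in dist[u]:
                assert dist[u][v] == dist[v][u]
                for w in nodes:
                    if w in dist[u] and w in dist[v]:
                        assert dist[u][w] <= dist[u][v] + dist[v][w]


class TestWithinSetDistances:
    def test_adjacent_pair(self, path_graph):
        d = within_set_distances(path_graph, {"a", "b"})
        assert d.counts == {1: 1}
        assert d.mean == 1.0

    def test_triangle_all_nodes(self, triangle_graph):
        d = within_set_distances(triangle_graph, {"a", "b", "c"})
        assert d.counts == {1: 3}
        assert d.mean == 1.0

    def test_within_module_below_background(self):
        g = gen_ppi(200, 4, p_in=0.3, p_out=0.02, seed=1)
        mod = module_map(g)
        members = {n for n, m in mod.items() if m == 0}
        within = within_set_distances(g, set(list(members)[:15]))
        bg = background_distances(g)
        assert within.mean < bg.mean

    def test_too_few_mapped_members(self, path_graph):
        with pytest.raises(ValueError, match="2"):
            within_set_distances(path_graph, {"a", "zz"})

    def test_unreachable_pairs_excluded(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_edge("x", "y")
        d = within_set_distances(g, {"a", "b", "x"})
        assert d.counts == {1: 1}
        assert d.excluded_infinite == 2


class TestBackgroundDistances:
    def test_path_graph(self, path_graph):
        d = background_distances(path_graph)
        assert d.counts == {1: 2, 2: 1}
        assert d.mean == pytest.approx(4 / 3)

    def test_complete_graph(self):
        d = background_distances(nx.complete_graph(5))
        assert d.counts == {1: 10}
        assert d.mean == 1.0

    def test_sampled_within_3se_of_exact(self):
        g = nx.gnp_random_graph(200, 0.04, seed=3)
        exact = background_distances(g)
        sampled = background_distances(g, exact_cap=10, n_samples=20000, seed=4)
        assert sampled.sampled
        var = (
            sum(c * (d - exact.mean) ** 2 for d, c in exact.counts.items())
            / exact.n_pairs
        )
        se = (var / sampled.n_pairs) ** 0.5
        assert abs(sampled.mean - exact.mean) < 3 * se + 0.01

    def test_sampling_deterministic_by_seed(self):
        g = nx.gnp_random_graph(50, 0.1, seed=5)
        a = background_distances(g, exact_cap=10, n_samples=500, seed=6)
        b = background_distances(g, exact_cap=10, n_samples=500, seed=6)
        assert a.counts == b.counts


class TestCrossSetDistances:
    def test_same_gene_distance_zero(self, path_graph):
        out = cross_set_distance_per_drug(path_graph, {"d": {"a"}}, {"d": {"a"}})
        assert out["d"].counts == {0: 1}
        assert out["d"].mean == 0.0

    def test_path_endpoints(self, path_graph):
        out = cross_set_distance_per_drug(path_graph, {"d": {"a"}}, {"d": {"c"}})
        assert out["d"].counts == {2: 1}
        assert out["d"].mean == 2.0

    def test_missing_drug_skipped_not_error(self, path_graph, caplog):
        out = cross_set_distance_per_drug(path_graph, {"d": {"a"}, "e": {"b"}}, {"d": {"c"}})
        assert set(out) == {"d"}

    def test_random_sets_match_bfs_oracle(self):
        g = nx.gnp_random_graph(40, 0.1, seed=8)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        rng = np.random.default_rng(9)
        nodes = sorted(g.nodes)
        sens = {"d": set(rng.choice(nodes, 5, replace=False))}
        targ = {"d": set(rng.choice(nodes, 4, replace=False))}
        out = cross_set_distance_per_drug(g, sens, targ)["d"]
        expected: dict[int, int] = {}
        infinite = 0
        for s in sorted(sens["d"]):
            sp = dict(nx.single_source_shortest_path_length(g, s))
            for t in sorted(targ["d"]):
                d = 0 if s == t else sp.get(t)
                if d is None:
                    infinite += 1
                else:
                    expected[d] = expected.get(d, 0) + 1
        assert out.counts == expected
        assert out.excluded_infinite == infinite


class TestDrugsBelowThreshold:
    def test_mean_zero_always_included(self, path_graph):
        per = cross_set_distance_per_drug(path_graph, {"d": {"a"}}, {"d": {"a"}})
        assert drugs_below_threshold(per, 0.5) == {"d"}

    def test_strict_inequality(self, path_graph):
        per = cross_set_distance_per_drug(path_graph, {"d": {"a"}}, {"d": {"c"}})
        assert drugs_below_threshold(per, 2.0) == set()
        assert drugs_below_threshold(per, 2.01) == {"d"}

    def test_overlap_of_two_networks(self):
        g1 = gen_ppi(60, 3, p_in=0.4, p_out=0.02, seed=10)
        g2 = gen_ppi(60, 3, p_in=0.4, p_out=0.02, seed=11)
        mod = module_map(g1)
        by_mod: dict[int, list[str]] = {}
        for g, m in sorted(mod.items()):
            by_mod.setdefault(m, []).append(g)
        sens = {f"d{m}": set(by_mod[m][:3]) for m in by_mod}
        targ = {f"d{m}": set(by_mod[m][3:5]) for m in by_mod}
        s1 = drugs_below_threshold(cross_set_distance_per_drug(g1, sens, targ), 4)
        s2 = drugs_below_threshold(cross_set_distance_per_drug(g2, sens, targ), 4)
        assert s1 & s2 == {d for d in s1 if d in s2}

    def test_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            drugs_below_threshold({}, 0)


class TestEgoSubgraph:
    def test_star_center(self):
        g = nx.star_graph(5)
        sub = ego_subgraph(g, 0)
        assert set(sub.nodes) == set(g.nodes)
        assert sub.number_of_edges() == 5

    def test_triangle_induced(self, triangle_graph):
        sub = ego_subgraph(triangle_graph, "a")
        assert set(sub.nodes) == {"a", "b", "c"}
        assert sub.number_of_edges() == 3  # includes the b-c edge

    def test_random_graph_matches_induced_oracle(self):
        g = nx.gnp_random_graph(30, 0.15, seed=12)
        for center in list(g.nodes)[:5]:
            sub = ego_subgraph(g, center)
            wanted = {center} | set(g.neighbors(center))
            oracle = g.subgraph(wanted)
            assert set(sub.nodes) == set(oracle.nodes)
            assert set(map(frozenset, sub.edges)) == set(map(frozenset, oracle.edges))

    def test_unknown_center(self, path_graph):
        with pytest.raises(KeyError):
            ego_subgraph(path_graph, "zz")
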