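"""Clustering, efficiency, random reference, small-world-ness, degree fits."""

import warnings
from collections import deque

import networkx as nx
import numpy as np
import pytest

import isletnet as isl
from isletnet import graphmetrics as gm


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def clustering_brute_force(g):
    """Triple loop over neighbor pairs."""
    out = {}
    for node in g.nodes():
        nbrs = list(g.neighbors(node))
        k = len(nbrs)
        if k < 2:
            out[node] = 0.0
            continue
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if g.has_edge(nbrs[a], nbrs[b])
        )
        out[node] = 2.0 * links / (k * (k - 1))
    return out


def efficiency_brute_force(g):
    """BFS shortest paths; disconnected pairs contribute zero."""
    nodes = list(g.nodes())
    n = len(nodes)
    total = 0.0
    for src in nodes:
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        total += sum(1.0 / d for node, d in dist.items() if d > 0)
    return total / (n * (n - 1))


class TestClustering:
    def test_triangle(self):
        ci, c_avg = gm.clustering_coefficients(nx.complete_graph(3))
        assert all(v == 1.0 for v in ci.values())
        assert c_avg == 1.0

    def test_path_has_zero_clustering(self):
        ci, c_avg = gm.clustering_coefficients(nx.path_graph(3))
        assert c_avg == 0.0

    def test_chorded_square(self):
        g = nx.cycle_graph(4)  # 0-1-2-3-0
        g.add_edge(0, 2)
        ci, c_avg = gm.clustering_coefficients(g)
        assert ci[0] == pytest.approx(2 / 3)
        assert ci[1] == pytest.approx(1.0)
        assert ci[2] == pytest.approx(2 / 3)
        assert ci[3] == pytest.approx(1.0)
        assert c_avg == pytest.approx(5 / 6)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(int(rng.integers(5, 30)), rng.uniform(0.1, 0.7),
                                    seed=int(rng.integers(2**31)))
            ci, c_avg = gm.clustering_coefficients(g)
            ref = clustering_brute_force(g)
            assert max(abs(ci[u] - ref[u]) for u in g.nodes()) < 1e-12


class TestGlobalEfficiency:
    def test_complete_graph_unity(self):
        assert gm.global_efficiency(nx.complete_graph(7)) == pytest.approx(1.0)

    def test_edgeless_graph_zero(self):
        assert gm.global_efficiency(nx.empty_graph(5)) == 0.0

    def test_path_of_three(self):
        assert gm.global_efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(int(rng.integers(5, 30)), rng.uniform(0.05, 0.5),
                                    seed=int(rng.integers(2**31)))
            assert gm.global_efficiency(g) == pytest.approx(
                efficiency_brute_force(g), abs=1e-12
            )


class TestRandomReference:
    def test_complete_and_empty_are_exact(self):
        assert gm.random_reference(6, 15) == (1.0, 1.0)
        assert gm.random_reference(6, 0) == (0.0, 0.0)

    def test_clustering_matches_edge_density(self):
        # uniform G(n, m): expected clustering equals the edge density
        n, m = 100, 990
        density = m / (n * (n - 1) / 2)
        rng = np.random.default_rng(3)
        samples = [
            gm.clustering_coefficients(
                nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            )[1]
            for _ in range(60)
        ]
        se = np.std(samples, ddof=1) / np.sqrt(len(samples))
        c_rand, _ = gm.random_reference(n, m, n_realizations=60, seed=7)
        assert abs(c_rand - density) < 3 * max(se, 1e-4)

    def test_deterministic_given_seed(self):
        a = gm.random_reference(20, 40, n_realizations=10, seed=5)
        b = gm.random_reference(20, 40, n_realizations=10, seed=5)
        assert a == b

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            gm.random_reference(5, 11)


class TestSmallWorldness:
    @pytest.mark.parametrize(
        "cr,er,s", [(5.59, 1.41, 3.96), (5.29, 2.84, 1.86), (4.28, 2.48, 1.73)]
    )
    def test_ratio_arithmetic(self, cr, er, s):
        assert round(gm.small_worldness_from_ratios(cr, er), 2) == s

    def test_random_graph_self_comparison_is_unity(self):
        out = gm.small_worldness(0.3, 0.5, 0.3, 0.5)
        assert out.s == pytest.approx(1.0)

    def test_consistency_of_stored_ratios(self):
        out = gm.small_worldness(0.67, 0.29, 0.12, 0.41)
        assert out.s == pytest.approx(
            out.clustering_ratio / out.efficiency_ratio, abs=1e-12
        )

    def test_zero_denominator_flagged_not_infinite(self):
        out = gm.small_worldness(0.5, 0.3, 0.0, 0.4)
        assert out.degenerate
        assert np.isnan(out.s)


class TestCumulativeDegreeDistribution:
    def test_hand_counted_example(self):
        # hub of degree 4, two leaves of degree 1, two nodes of degree 2
        h = nx.Graph()
        h.add_edges_from([("hub", "a"), ("hub", "b"), ("hub", "c"), ("hub", "d"),
                          ("c", "d")])
        degrees = sorted(d for _, d in h.degree())
        assert degrees == [1, 1, 2, 2, 4]
        out = gm.cumulative_degree_distribution(
            h, grid=np.array([0.25, 0.5, 0.75, 1.0])
        )
        assert out.G.tolist() == [1.0, 0.6, 0.2, 0.2]

    def test_equal_degrees_step_function(self):
        g = nx.cycle_graph(6)  # all degree 2
        out = gm.cumulative_degree_distribution(g, grid=np.array([0.5, 1.0]))
        assert out.G.tolist() == [1.0, 1.0]

    def test_two_identical_islets_pool_to_same_curve(self):
        g = nx.path_graph(5)
        single = gm.cumulative_degree_distribution(g)
        pooled = gm.cumulative_degree_distribution([g, g.copy()])
        assert np.array_equal(single.G, pooled.G)
        assert pooled.pooled

    def test_empty_graph_excluded_with_warning(self):
        g1, g2 = nx.path_graph(4), nx.empty_graph(4)
        with pytest.warns(UserWarning, match="excluded"):
            out = gm.cumulative_degree_distribution([g1, g2])
        assert out.excluded_islets == [1]


class TestDegreeFits:
    @staticmethod
    def _dist(G, grid):
        return gm.DegreeDistribution(
            grid=grid, G=G, curves=G[None, :], pooled=False
        )

    def test_exact_truncated_power_law_recovered(self):
        x = np.linspace(0.1, 1.0, 15)
        G = 0.9 * x**-1.0 * np.exp(-x / 0.5)
        fits = {f.model: f for f in gm.fit_degree_models(self._dist(G, x))}
        best = fits["truncated_power_law"]
        assert best.best
        assert best.r2 >= 0.999
        assert best.alpha == pytest.approx(1.0, abs=1e-6)
        assert best.kappa == pytest.approx(0.5, abs=1e-6)

    def test_pure_exponential_beats_power_law(self):
        x = np.linspace(0.1, 1.0, 15)
        G = 1.2 * np.exp(-x / 0.3)
        fits = {f.model: f for f in gm.fit_degree_models(self._dist(G, x))}
        assert fits["exponential"].r2 >= fits["power_law"].r2

    def test_truncated_model_nests_the_other_two(self, rng):
        x = np.linspace(0.1, 1.0, 12)
        G = np.exp(-x / 0.4) * np.exp(rng.normal(0, 0.1, size=x.size))
        fits = {f.model: f for f in gm.fit_degree_models(self._dist(G, x))}
        assert fits["truncated_power_law"].r2 >= fits["power_law"].r2 - 1e-12
        assert fits["truncated_power_law"].r2 >= fits["exponential"].r2 - 1e-12

    def test_exactly_one_best_model(self, rng):
        x = np.linspace(0.1, 1.0, 10)
        G = np.exp(-x) * np.exp(rng.normal(0, 0.05, size=x.size))
        fits = gm.fit_degree_models(self._dist(G, x))
        assert sum(f.best for f in fits) == 1

    def test_too_few_points_rejected(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])
        with pytest.raises(ValueError, match=">= 5"):
            gm.fit_degree_models(self._dist(np.exp(-x), x))
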