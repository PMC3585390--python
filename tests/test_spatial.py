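"""Distance matrices, 2-D histograms, binned correlations, hub link lengths."""

import math

import networkx as nx
import numpy as np
import pytest

import isletnet as isl
from isletnet import spatial
from isletnet.network import CorrelationMatrix, FunctionalNetwork


def _corr(R, ids):
    return CorrelationMatrix(R=R, cell_ids=list(ids), n_samples=100)


def _net(edges, ids, weights=0.9):
    g = nx.Graph()
    g.add_nodes_from(ids)
    for u, v in edges:
        g.add_edge(u, v, weight=weights)
    return FunctionalNetwork(graph=g, r_th=0.75, cell_ids=list(ids))


class TestPairwiseDistances:
    def test_three_four_five(self):
        cm = isl.CellMap.from_arrays([0, 1], [0.0, 3.0], [0.0, 4.0])
        assert isl.pairwise_distances(cm).l[0, 1] == pytest.approx(5.0)

    def test_coincident_points(self):
        cm = isl.CellMap.from_arrays([0, 1], [2.0, 2.0], [7.0, 7.0])
        assert isl.pairwise_distances(cm).l[0, 1] == 0.0

    def test_matches_brute_force(self, rng):
        xy = rng.uniform(-100, 100, size=(20, 2))
        cm = isl.CellMap.from_arrays(range(20), xy[:, 0], xy[:, 1])
        l = isl.pairwise_distances(cm).l
        for i in range(20):
            for j in range(20):
                ref = math.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
                assert abs(l[i, j] - ref) < 1e-12

    def test_rigid_motion_invariance(self, rng):
        xy = rng.uniform(-50, 50, size=(15, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = xy @ rot.T + np.array([123.0, -45.0])
        a = isl.pairwise_distances(isl.CellMap.from_arrays(range(15), *xy.T)).l
        b = isl.pairwise_distances(isl.CellMap.from_arrays(range(15), *moved.T)).l
        assert np.abs(a - b).max() < 1e-9


class TestHist2D:
    def test_total_count_conservation(self, rng):
        n = 12
        xy = rng.uniform(0, 100, size=(n, 2))
        cm = isl.CellMap.from_arrays(range(n), xy[:, 0], xy[:, 1])
        R = rng.uniform(-1, 1, size=(n, n))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        counts, *_, overflow = isl.hist2d_distance_correlation(
            isl.pairwise_distances(cm), _corr(R, range(n))
        )
        assert counts.sum() + overflow == n * (n - 1) / 2

    def test_all_pairs_in_one_bin(self):
        cm = isl.CellMap.from_arrays([0, 1, 2], [0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        counts, *_, overflow = isl.hist2d_distance_correlation(
            isl.pairwise_distances(cm), _corr(R, range(3)),
            d_edges=np.array([0.0, 5.0]), r_edges=np.array([0.0, 1.0]),
        )
        assert counts[0, 0] == 3
        assert overflow == 0

    def test_out_of_range_pairs_counted_as_overflow(self):
        cm = isl.CellMap.from_arrays([0, 1, 2], [0.0, 1.0, 50.0], [0.0, 0.0, 0.0])
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        counts, *_, overflow = isl.hist2d_distance_correlation(
            isl.pairwise_distances(cm), _corr(R, range(3)),
            d_edges=np.array([0.0, 5.0]), r_edges=np.array([0.0, 1.0]),
        )
        assert counts.sum() == 1  # only the (0,1) pair is within 5 µm
        assert overflow == 2

    def test_nonmonotone_edges_rejected(self):
        cm = isl.CellMap.from_arrays([0, 1], [0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="increasing"):
            isl.hist2d_distance_correlation(
                isl.pairwise_distances(cm), _corr(np.eye(2), range(2)),
                d_edges=np.array([10.0, 0.0]),
            )


class TestDistanceBinnedCorrelation:
    def test_uniform_correlation_everywhere(self, rng):
        n = 8
        xy = rng.uniform(0, 100, size=(n, 2))
        cm = isl.CellMap.from_arrays(range(n), xy[:, 0], xy[:, 1])
        R = np.full((n, n), 0.37)
        np.fill_diagonal(R, 1.0)
        out = isl.distance_binned_avg_correlation(
            isl.pairwise_distances(cm), _corr(R, range(n))
        )
        filled = out.dropna(subset=["mean_r"])
        assert np.allclose(filled.mean_r, 0.37)

    def test_two_bin_direct_example(self):
        cm = isl.CellMap.from_arrays([0, 1, 2], [0.0, 10.0, 100.0], [0.0, 0.0, 0.0])
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.2   # 10 µm pair
        R[0, 2] = R[2, 0] = 0.8   # 100 µm pair
        R[1, 2] = R[2, 1] = 0.8   # 90 µm pair
        out = isl.distance_binned_avg_correlation(
            isl.pairwise_distances(cm), _corr(R, range(3)),
            d_edges=np.array([0.0, 50.0, 150.0]),
        )
        assert out.mean_r.tolist() == [0.2, 0.8]
        assert out.n_pairs.tolist() == [1, 2]

    def test_empty_bins_missing_not_zero(self):
        cm = isl.CellMap.from_arrays([0, 1], [0.0, 100.0], [0.0, 0.0])
        out = isl.distance_binned_avg_correlation(
            isl.pairwise_distances(cm), _corr(np.eye(2), range(2)),
            d_edges=np.array([0.0, 10.0, 90.0, 110.0]),
        )
        assert np.isnan(out.mean_r.iloc[0]) and np.isnan(out.mean_r.iloc[1])
        assert out.n_pairs.iloc[:2].tolist() == [0, 0]


class TestHubLinkLengths:
    def _star(self):
        # hub 0 at origin, 4 spokes at 10 µm
        cm = isl.CellMap.from_arrays(
            range(5), [0.0, 10.0, -10.0, 0.0, 0.0], [0.0, 0.0, 0.0, 10.0, -10.0]
        )
        net = _net([(0, i) for i in range(1, 5)], range(5))
        return net, isl.pairwise_distances(cm)

    def test_star_graph_hub(self):
        net, dist = self._star()
        assert isl.hub_link_lengths(net, dist) == pytest.approx(10.0)

    def test_complete_graph_equal_lengths_selection_irrelevant(self):
        # equilateral complete graph: whichever nodes are picked as hubs,
        # the answer is the common edge length = the mean over all edges
        cm = isl.CellMap.from_arrays(
            range(3), [0.0, 10.0, 5.0], [0.0, 0.0, 5 * math.sqrt(3)]
        )
        dist = isl.pairwise_distances(cm)
        net = _net([(0, 1), (1, 2), (0, 2)], range(3))
        expected = dist.offdiag_values().mean()
        assert isl.hub_link_lengths(net, dist, top_fraction=0.2) == pytest.approx(expected)

    def test_five_node_enumeration(self, rng):
        # degrees (4, 2, 2, 1, 1): top 20% = 1 node = the hub; the mean runs
        # over the hub's 4 incident edges, enumerated by hand
        xy = rng.uniform(0, 100, size=(5, 2))
        cm = isl.CellMap.from_arrays(range(5), xy[:, 0], xy[:, 1])
        dist = isl.pairwise_distances(cm)
        edges = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2)]
        net = _net(edges, range(5))
        assert net.degrees.tolist() == [4, 2, 2, 1, 1]
        expected = np.mean([dist.l[0, j] for j in (1, 2, 3, 4)])
        assert isl.hub_link_lengths(net, dist, top_fraction=0.2) == pytest.approx(expected)

    def test_edgeless_network_is_nan(self):
        cm = isl.CellMap.from_arrays(range(3), [0.0, 1.0, 2.0], [0.0] * 3)
        net = _net([], range(3))
        assert math.isnan(isl.hub_link_lengths(net, isl.pairwise_distances(cm)))


class TestClusteringVsLinkLength:
    def test_uniform_edge_length(self):
        cm = isl.CellMap.from_arrays(range(3), [0.0, 10.0, 5.0],
                                     [0.0, 0.0, 5 * math.sqrt(3)])
        net = _net([(0, 1), (1, 2), (0, 2)], range(3))  # equilateral triangle
        out = isl.clustering_vs_link_length(net, isl.pairwise_distances(cm))
        filled = out.dropna(subset=["mean_link_length_um"])
        assert np.allclose(filled.mean_link_length_um, 10.0)

    def test_triangle_plus_far_pair(self):
        # 10-µm triangle (C_i = 1) and a detached 100-µm pair (C_i = 0)
        cm = isl.CellMap.from_arrays(
            range(5),
            [0.0, 10.0, 5.0, 200.0, 300.0],
            [0.0, 0.0, 5 * math.sqrt(3), 0.0, 0.0],
        )
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4)], range(5))
        out = isl.clustering_vs_link_length(
            net, isl.pairwise_distances(cm), c_edges=np.array([0.0, 0.5, 1.0])
        )
        assert out.mean_link_length_um.iloc[0] == pytest.approx(100.0)  # C in [0,.5)
        assert out.mean_link_length_um.iloc[1] == pytest.approx(10.0)   # C in [.5,1]

    def test_degree_zero_nodes_excluded(self):
        cm = isl.CellMap.from_arrays(range(3), [0.0, 10.0, 500.0], [0.0] * 3)
        net = _net([(0, 1)], range(3))
        out = isl.clustering_vs_link_length(net, isl.pairwise_distances(cm))
        assert out.n_cells.sum() == 2

    def test_edgeless_network_rejected(self):
        cm = isl.CellMap.from_arrays(range(3), [0.0, 1.0, 2.0], [0.0] * 3)
        with pytest.raises(ValueError, match="no links"):
            isl.clustering_vs_link_length(_net([], range(3)),
                                          isl.pairwise_distances(cm))
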