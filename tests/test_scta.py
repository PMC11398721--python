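"""Synchronization cluster tracking: construction, lineage, statistics."""

import networkx as nx
import numpy as np
import pytest

import tesnet as tn
from tesnet.dynamics import local_order
from tesnet.scta import Cluster, ClusterSnapshot


def binary_graph(a):
    return tn.NetworkGraph(np.asarray(a, float))


def path_graph(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return tn.NetworkGraph(w)


def window_of(theta_panel, r_panel, stride=1.0):
    theta_panel = np.asarray(theta_panel, float)
    return tn.TransientWindow(
        onset_time=0.0, duration=(theta_panel.shape[0] - 1) * stride,
        stride=stride, theta_panel=theta_panel,
        r_panel=np.asarray(r_panel, float))


def components_oracle(g, supra):
    """Connected components of the supra-threshold induced subgraph."""
    und = nx.from_numpy_array(g.skeleton())
    sub = und.subgraph(np.flatnonzero(supra))
    return {frozenset(c) for c in nx.connected_components(sub)}


class TestFindClusters:
    def test_threshold_validation(self):
        g = path_graph(3)
        with pytest.raises(ValueError):
            tn.find_clusters(np.zeros(3), g, threshold=0.0)

    def test_fully_synchronized_connected_graph(self):
        g = path_graph(6)
        snap = tn.find_clusters(np.zeros(6), g, threshold=0.5)
        assert len(snap.clusters) == 1
        assert sorted(snap.clusters[0].members) == list(range(6))
        assert snap.unclustered == set()

    def test_all_subthreshold_gives_no_clusters(self):
        g = path_graph(4)
        snap = tn.find_clusters(np.zeros(4), g, threshold=0.5,
                                _r=np.full(4, 0.2))
        assert snap.clusters == []
        assert snap.unclustered == set(range(4))

    def test_six_node_path_split(self):
        g = path_graph(6)
        r = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
        snap = tn.find_clusters(np.zeros(6), g, threshold=0.5, _r=r)
        assert {frozenset(c.members) for c in snap.clusters} == \
            {frozenset({0, 1, 2})}
        assert snap.unclustered == {3, 4, 5}

    @pytest.mark.parametrize("seed", range(20))
    def test_member_sets_equal_induced_components(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        a = (rng.random((n, n)) < 0.35)
        a = np.triu(a, 1)
        a = (a + a.T).astype(float)
        g = binary_graph(a)
        for _ in range(5):
            theta = rng.uniform(0, 2 * np.pi, n)
            r = local_order(theta, g)
            snap = tn.find_clusters(theta, g, threshold=0.5)
            got = {frozenset(c.members) for c in snap.clusters}
            assert got == components_oracle(g, r >= 0.5)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        g = binary_graph(nx.to_numpy_array(nx.erdos_renyi_graph(15, 0.3,
                                                                seed=2)))
        theta = rng.uniform(0, 2 * np.pi, 15)
        lo = tn.find_clusters(theta, g, threshold=0.3)
        hi = tn.find_clusters(theta, g, threshold=0.6)
        for ch in hi.clusters:
            assert any(set(ch.members) <= set(cl.members)
                       for cl in lo.clusters)

    def test_central_nodes_are_top_r_members(self):
        g = path_graph(8)
        theta = np.zeros(8)
        snap = tn.find_clusters(theta, g, threshold=0.5)
        c = snap.clusters[0]
        r = local_order(theta, g)
        assert len(c.central) == 5
        assert set(c.central) <= set(c.members)
        worst_central = min(r[i] for i in c.central)
        outside = [r[i] for i in c.members if i not in c.central]
        assert all(worst_central >= v for v in outside)

    def test_id_inheritance_through_central_nodes(self):
        g = path_graph(4)
        prev = ClusterSnapshot(0.0, [Cluster(7, [0, 1, 2, 3], [1, 2])],
                               set())
        r = np.array([0.9, 0.9, 0.9, 0.9])
        snap = tn.find_clusters(np.zeros(4), g, threshold=0.5, prev=prev,
                                _r=r)
        assert snap.clusters[0].id == 7

    def test_split_cluster_highest_r_central_keeps_id(self):
        # previous cluster spanned the whole path; now the middle is
        # sub-threshold, splitting it in two; the half holding the
        # higher-r central node inherits id 3, the other gets a new id
        g = path_graph(7)
        prev = ClusterSnapshot(0.0, [Cluster(3, list(range(7)), [1, 5])],
                               set())
        r = np.array([0.9, 0.8, 0.9, 0.1, 0.9, 0.95, 0.9])
        snap = tn.find_clusters(np.zeros(7), g, threshold=0.5, prev=prev,
                                _r=r)
        by_members = {frozenset(c.members): c.id for c in snap.clusters}
        assert by_members[frozenset({4, 5, 6})] == 3
        assert by_members[frozenset({0, 1, 2})] != 3


class TestTrackClusters:
    def test_static_synchronized_window(self):
        g = path_graph(5)
        theta = np.zeros((11, 5))
        r = np.ones((11, 5))
        ln = tn.track_clusters(window_of(theta, r), g, eval_stride=1.0)
        np.testing.assert_allclose(ln.time_in_main, ln.duration)
        assert len(set(ln.main_cluster_ids)) == 1  # persistent identity

    def test_static_incoherent_window(self):
        g = path_graph(5)
        ln = tn.track_clusters(window_of(np.zeros((11, 5)),
                                         np.zeros((11, 5))), g,
                               eval_stride=1.0)
        np.testing.assert_array_equal(ln.time_in_main, 0.0)
        assert all(m is None for m in ln.main_cluster_ids)

    def test_two_epoch_window_membership_time(self):
        # A,B,C synchronized throughout; D joins for the second half
        w = np.ones((4, 4)) - np.eye(4)
        g = binary_graph(w)
        T = 10
        r = np.ones((T, 4))
        r[:5, 3] = 0.2
        ln = tn.track_clusters(window_of(np.zeros((T, 4)), r, stride=1.0),
                               g, eval_stride=1.0)
        dur = ln.duration
        np.testing.assert_allclose(ln.time_in_main[:3], dur)
        assert ln.time_in_main[3] == pytest.approx(dur * 5 / T)

    def test_partition_at_every_instant(self, connectome, fixture_windows):
        ln = tn.track_clusters(fixture_windows[0], connectome,
                               eval_stride=1.0)
        n = connectome.n_nodes
        for snap in ln.snapshots:
            seen = [m for c in snap.clusters for m in c.members]
            assert len(seen) == len(set(seen))  # disjoint
            assert set(seen) | snap.unclustered == set(range(n))

    def test_stride_validation(self, fixture_windows, connectome):
        with pytest.raises(ValueError):
            tn.track_clusters(fixture_windows[0], connectome,
                              eval_stride=0.3)


class TestStats:
    def _lineage(self, times):
        ln = tn.ClusterLineage([], np.asarray(times, float), 50.0, 0.2)
        return ln

    def test_single_lineage_zero_variance(self):
        stats = tn.time_in_main_stats([self._lineage([10.0, 20.0])])
        assert list(stats["median"]) == [10.0, 20.0]
        assert list(stats["variance"]) == [0.0, 0.0]

    def test_two_lineages_population_variance(self):
        stats = tn.time_in_main_stats([self._lineage([10.0]),
                                       self._lineage([30.0])])
        assert stats["median"].iloc[0] == 20.0
        assert stats["variance"].iloc[0] == 100.0  # divide-by-n convention

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tn.time_in_main_stats([])


class TestDriverNodes:
    def _graph_with_out_degrees(self, degs):
        n = len(degs) + max(degs) + 1
        w = np.zeros((n, n))
        for j, d in enumerate(degs):
            for t in range(d):
                w[len(degs) + t, j] = 1.0
        return tn.NetworkGraph(w, directed=True)

    def test_threshold_logic(self):
        import pandas as pd
        g = self._graph_with_out_degrees([40, 100, 50])
        stats = pd.DataFrame({
            "node": np.arange(g.n_nodes),
            "median": np.zeros(g.n_nodes),
            "variance": np.zeros(g.n_nodes)})
        stats.loc[0, "median"] = 45.0
        stats.loc[0, "variance"] = 10.0
        stats.loc[1, "median"] = 5.0     # high out-degree, low residence
        stats.loc[2, "median"] = 45.0
        stats.loc[2, "variance"] = 100.0  # too variable
        assert tn.driver_nodes(stats, g) == [0]

    def test_empty_stats(self):
        import pandas as pd
        g = path_graph(2)
        empty = pd.DataFrame(columns=["node", "median", "variance"])
        assert tn.driver_nodes(empty, g) == []

    def test_sorted_by_median_descending(self):
        import pandas as pd
        g = self._graph_with_out_degrees([40, 40])
        stats = pd.DataFrame({"node": np.arange(g.n_nodes),
                              "median": 0.0, "variance": 0.0})
        stats.loc[0, "median"] = 40.0
        stats.loc[1, "median"] = 45.0
        assert tn.driver_nodes(stats, g) == [1, 0]
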