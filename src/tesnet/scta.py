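"""Synchronization Cluster Tracking Algorithm (SCTA).

At every evaluation instant, synchronization clusters are built by
threshold-gated expansion over the undirected skeleton of the network:
a node can join a cluster only if its own local synchrony r_i is at or
above the threshold, and the expansion frontier passes only through
nodes that have joined (a sub-threshold node blocks the path).  The
resulting member sets are exactly the connected components of the
subgraph induced by the supra-threshold nodes; what the seeded
expansion adds is *identity*: each cluster carries up to five central
nodes (its highest-r members) forward in time, so clusters can be
tracked as lineages across the whole transient.

The largest cluster at each instant is the *main synchronization
cluster*; the per-node residence time in it, aggregated across
transients, identifies core nodes, and combined with out-degree the
putative driver nodes of hypersynchronization.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import local_order
from .graph import NetworkGraph
from .transients import TransientWindow

__all__ = ["Cluster", "ClusterSnapshot", "ClusterLineage", "find_clusters",
           "track_clusters", "time_in_main_stats", "driver_nodes"]

MAX_CENTRAL = 5


@dataclass
class Cluster:
    id: int
    members: list[int]
    central: list[int]   # up to 5 members with highest r, descending


@dataclass
class ClusterSnapshot:
    time: float
    clusters: list[Cluster]
    unclustered: set[int]

    def cluster_of(self) -> dict[int, int]:
        return {m: c.id for c in self.clusters for m in c.members}

    @property
    def main_cluster_id(self) -> Optional[int]:
        """Largest cluster; ties broken toward the smallest id."""
        if not self.clusters:
            return None
        return min(self.clusters, key=lambda c: (-len(c.members), c.id)).id


@dataclass
class ClusterLineage:
    """Time-ordered snapshots with persistent cluster ids, plus the
    per-node residence time in the main cluster over the window."""

    snapshots: list[ClusterSnapshot]
    time_in_main: np.ndarray     # per node, in time units
    duration: float
    eval_stride: float

    @property
    def main_cluster_ids(self) -> list[Optional[int]]:
        return [s.main_cluster_id for s in self.snapshots]

    def sizes(self) -> pd.DataFrame:
        rows = [{"time": s.time, "cluster": c.id, "size": len(c.members)}
                for s in self.snapshots for c in s.clusters]
        return pd.DataFrame(rows, columns=["time", "cluster", "size"])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"time": s.time, "cluster": c.id, "node": m}
                for s in self.snapshots for c in s.clusters
                for m in c.members]
        return pd.DataFrame(rows, columns=["time", "cluster", "node"])


# ---------------------------------------------------------------------
# per-instant clustering
# ---------------------------------------------------------------------

def _adjacency_lists(g: NetworkGraph) -> list[np.ndarray]:
    a = g.skeleton()
    return [np.flatnonzero(a[i]) for i in range(g.n_nodes)]


def _expand(seed: int, supra: np.ndarray, assigned: np.ndarray,
            adj: list[np.ndarray]) -> list[int]:
    """BFS over supra-threshold unassigned nodes starting at ``seed``."""
    members = [seed]
    assigned[seed] = True
    queue = deque([seed])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if supra[v] and not assigned[v]:
                assigned[v] = True
                members.append(int(v))
                queue.append(int(v))
    return members


def find_clusters(theta_t: np.ndarray, g: NetworkGraph,
                  threshold: float = 0.5,
                  prev: Optional[ClusterSnapshot] = None,
                  time: float = 0.0,
                  _next_id: Optional[list[int]] = None,
                  _adj: Optional[list[np.ndarray]] = None,
                  _r: Optional[np.ndarray] = None) -> ClusterSnapshot:
    """Build the synchronization clusters for one phase snapshot.

    Step 1: previous clusters, processed in descending previous size
    (ties toward smaller id), re-seed an expansion from their central
    nodes — the central node with highest current r that is itself
    supra-threshold and unassigned starts a breadth-first expansion and
    the grown cluster inherits the previous id.  Step 2: remaining
    supra-threshold unassigned nodes seed fresh clusters in descending
    r order.  Step 3: each cluster's central-node list is recomputed as
    its up-to-five members of highest r.  Nodes with r below the
    threshold stay unclustered.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    r = local_order(theta_t, g) if _r is None else _r
    supra = r >= threshold
    adj = _adjacency_lists(g) if _adj is None else _adj
    n = g.n_nodes
    assigned = np.zeros(n, dtype=bool)
    clusters: list[Cluster] = []
    counter = _next_id if _next_id is not None else [0]

    if prev is not None:
        order = sorted(prev.clusters, key=lambda c: (-len(c.members), c.id))
        for pc in order:
            cands = [c for c in pc.central if supra[c] and not assigned[c]]
            if not cands:
                continue
            seed = max(cands, key=lambda c: r[c])
            members = _expand(seed, supra, assigned, adj)
            clusters.append(Cluster(pc.id, members, []))
            counter[0] = max(counter[0], pc.id + 1)

    for seed in np.argsort(-r):
        seed = int(seed)
        if not supra[seed] or assigned[seed]:
            continue
        members = _expand(seed, supra, assigned, adj)
        clusters.append(Cluster(counter[0], members, []))
        counter[0] += 1

    for c in clusters:
        c.members.sort()
        top = sorted(c.members, key=lambda i: -r[i])[:MAX_CENTRAL]
        c.central = top
    unclustered = set(np.flatnonzero(~supra).tolist())
    return ClusterSnapshot(time=time, clusters=clusters,
                           unclustered=unclustered)


# ---------------------------------------------------------------------
# tracking across a window
# ---------------------------------------------------------------------

def track_clusters(window: TransientWindow, g: NetworkGraph,
                   threshold: float = 0.5,
                   eval_stride: float = 0.2) -> ClusterLineage:
    """Apply the cluster construction at every evaluation instant of a
    transient window, carrying central nodes forward so cluster ids
    persist through time.

    ``time_in_main`` for a node is the window duration multiplied by
    the fraction of evaluation instants at which the node belonged to
    the main (largest) cluster.
    """
    every = round(eval_stride / window.stride)
    if every < 1 or abs(every * window.stride - eval_stride) > 1e-9:
        raise ValueError("eval_stride must be a multiple of the window stride")
    adj = _adjacency_lists(g)
    counter = [0]
    snapshots: list[ClusterSnapshot] = []
    in_main = np.zeros(g.n_nodes)
    prev = None
    idx = range(0, window.n_samples, every)
    for k in idx:
        # r is recorded in the window; recomputing from theta gives the
        # same values, but the recorded panel is authoritative
        snap = find_clusters(window.theta_panel[k], g, threshold=threshold,
                             prev=prev, time=float(k * window.stride),
                             _next_id=counter, _adj=adj,
                             _r=window.r_panel[k])
        main = snap.main_cluster_id
        if main is not None:
            for c in snap.clusters:
                if c.id == main:
                    in_main[c.members] += 1.0
        snapshots.append(snap)
        prev = snap
    n_inst = len(snapshots)
    time_in_main = in_main / n_inst * window.duration
    return ClusterLineage(snapshots=snapshots, time_in_main=time_in_main,
                          duration=window.duration, eval_stride=eval_stride)


def time_in_main_stats(lineages: Sequence[ClusterLineage]) -> pd.DataFrame:
    """Per-node median and variance of the time spent in the main
    cluster across transients (population variance, divide by n)."""
    if not lineages:
        raise ValueError("need at least one lineage")
    mat = np.vstack([ln.time_in_main for ln in lineages])
    return pd.DataFrame({
        "node": np.arange(mat.shape[1]),
        "median": np.median(mat, axis=0),
        "variance": mat.var(axis=0, ddof=0),
    })


def driver_nodes(stats: pd.DataFrame, g: NetworkGraph,
                 min_out_degree: float = 30, min_median: float = 35,
                 max_variance: float = 49) -> list[int]:
    """Putative driver nodes of hypersynchronization: out-degree above
    ``min_out_degree``, median residence time above ``min_median`` and
    variance below ``max_variance``; sorted by median, descending."""
    if len(stats) == 0:
        return []
    if len(stats) != g.n_nodes:
        raise ValueError("stats and graph node sets differ")
    out_deg = g.out_degree
    sel = stats[(out_deg[stats["node"].to_numpy()] > min_out_degree)
                & (stats["median"] > min_median)
                & (stats["variance"] < max_variance)]
    sel = sel.sort_values("median", ascending=False)
    return sel["node"].astype(int).tolist()


def lineage_stats_table(lineages: Sequence[ClusterLineage],
                        g: NetworkGraph, min_out_degree: float = 30,
                        min_median: float = 35,
                        max_variance: float = 49) -> pd.DataFrame:
    """Per-node summary: median/variance of time in main cluster,
    out-degree, and a driver flag."""
    stats = time_in_main_stats(lineages)
    drivers = set(driver_nodes(stats, g, min_out_degree, min_median,
                               max_variance))
    stats["out_degree"] = g.out_degree[stats["node"].to_numpy()]
    stats["driver"] = stats["node"].isin(drivers)
    return stats
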