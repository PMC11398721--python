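"""Structure-based community detection and intra-/intermodular
synchrony statistics.

Communities are found with the Louvain algorithm on the (max-)
symmetrized weighted graph.  Synchrony statistics are phase-coherence
measures evaluated per community (or community pair) at each time point
of an onset-aligned window and averaged across transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import NetworkGraph
from .transients import TransientWindow

__all__ = ["CommunityPartition", "detect_communities",
           "intramodular_synchrony", "intermodular_synchrony"]


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity score."""

    community_of_node: dict[int, int]
    n_communities: int
    modularity: float
    resolution: float = 1.0
    labels: Optional[dict[int, str]] = None

    def members(self, c: int) -> np.ndarray:
        return np.array(sorted(i for i, ci in self.community_of_node.items()
                               if ci == c))

    @property
    def communities(self) -> list[int]:
        return sorted(set(self.community_of_node.values()))

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.community_of_node.items())
        return pd.DataFrame(items, columns=["node", "community"])


def detect_communities(g: NetworkGraph, resolution: float = 1.0,
                       seed: int = 0) -> CommunityPartition:
    """Louvain partition of the symmetrized weighted graph.

    Directed weights are symmetrized with max(w_ij, w_ji).  The
    reported modularity is evaluated directly on the returned partition
    (same resolution), so it is self-consistent by construction.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    w = np.maximum(g.weights, g.weights.T)
    G = nx.from_numpy_array(w)
    comms = nx.community.louvain_communities(G, weight="weight",
                                             resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda s: (-len(s), min(s)))
    mapping = {int(node): ci for ci, nodes in enumerate(comms)
               for node in nodes}
    q = nx.community.modularity(G, comms, weight="weight",
                                resolution=resolution)
    return CommunityPartition(mapping, len(comms), float(q),
                              resolution=resolution)


# ---------------------------------------------------------------------
# synchrony statistics
# ---------------------------------------------------------------------

def _community_phasors(window: TransientWindow, part: CommunityPartition
                       ) -> dict[int, np.ndarray]:
    """Mean phasor time series P_c(t) = (1/N_c) Σ_{i∈c} e^{iθ_i(t)}."""
    z = np.exp(1j * window.theta_panel)
    out = {}
    for c in part.communities:
        idx = part.members(c)
        if idx.size == 0:
            raise ValueError(f"community {c} is empty")
        out[c] = z[:, idx].mean(axis=1)
    return out


def intramodular_synchrony(windows: Sequence[TransientWindow],
                           part: CommunityPartition,
                           per_trial: bool = False) -> pd.DataFrame:
    """Intramodular synchrony IMS_c(t) = |P_c(t)|, trial-averaged.

    Returns a long-format frame (time, community, mean, sd, n_trials),
    or (time, community, trial, value) when ``per_trial`` is set.
    """
    if not windows:
        raise ValueError("need at least one window")
    _check_shapes(windows, part)
    times = windows[0].times
    rows = []
    per = {c: [] for c in part.communities}
    for tr, w in enumerate(windows):
        ph = _community_phasors(w, part)
        for c, z in ph.items():
            per[c].append(np.abs(z))
    if per_trial:
        for c, vals in per.items():
            for tr, v in enumerate(vals):
                rows.extend({"time": t, "community": c, "trial": tr,
                             "value": x} for t, x in zip(times, v))
        return pd.DataFrame(rows)
    for c, vals in per.items():
        arr = np.asarray(vals)
        rows.extend({"time": t, "community": c, "mean": m, "sd": s,
                     "n_trials": len(vals)}
                    for t, m, s in zip(times, arr.mean(0), arr.std(0)))
    return pd.DataFrame(rows)


def intermodular_synchrony(windows: Sequence[TransientWindow],
                           part: CommunityPartition) -> pd.DataFrame:
    """Intermodular synchrony between community pairs, trial-averaged.

    For communities c1, c2 with mean phasors P_1, P_2 the statistic is
    the modulus of the average pairwise phasor mean,

        IMS_{c1,c2} = (1/(N_1 N_2)) |Σ_i Σ_j (e^{iθ_i} + e^{iθ_j})/2|
                    = |(P_1 + P_2) / 2|,

    computed here in the algebraically simplified form (the literal
    double sum factorises exactly).  Symmetric in (c1, c2); equals the
    intramodular statistic when c1 = c2.
    """
    if not windows:
        raise ValueError("need at least one window")
    _check_shapes(windows, part)
    times = windows[0].times
    comms = part.communities
    acc: dict[tuple[int, int], list[np.ndarray]] = \
        {pair: [] for pair in combinations(comms, 2)}
    for w in windows:
        ph = _community_phasors(w, part)
        for c1, c2 in acc:
            acc[(c1, c2)].append(np.abs(0.5 * (ph[c1] + ph[c2])))
    rows = []
    for (c1, c2), vals in acc.items():
        arr = np.asarray(vals)
        rows.extend({"time": t, "community_1": c1, "community_2": c2,
                     "mean": m, "sd": s, "n_trials": len(vals)}
                    for t, m, s in zip(times, arr.mean(0), arr.std(0)))
    return pd.DataFrame(rows)


def _check_shapes(windows: Sequence[TransientWindow],
                  part: CommunityPartition) -> None:
    shape = windows[0].theta_panel.shape
    if any(w.theta_panel.shape != shape for w in windows):
        raise ValueError("windows must share the same panel shape")
    n = shape[1]
    if set(part.community_of_node) != set(range(n)):
        raise ValueError("partition must cover exactly the window's nodes")


def time_to_half_max(df: pd.DataFrame, community: int) -> float:
    """First time at which a community's trial-averaged synchrony
    reaches half of its final (plateau) value; inf if it never does.

    Convenience for comparing how early communities join a
    propagating synchronization wave.
    """
    sub = df[df["community"] == community].sort_values("time")
    target = sub["mean"].iloc[-1] / 2.0
    hit = sub[sub["mean"] >= target]
    return float(hit["time"].iloc[0]) if len(hit) else float("inf")
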