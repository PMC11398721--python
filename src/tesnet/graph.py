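"""Network construction, connectome loading, and graph metrics.

Networks are stored as dense weight matrices with the *row = target*
convention: ``weights[i, j]`` is the strength with which node ``j``
influences node ``i`` (it enters node ``i``'s input sum).  Generated
benchmark families (small-world, scale-free, random) are binary and
undirected; connectomes may be weighted and directed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkGraph", "GraphMetrics", "make_small_world", "make_scale_free",
    "make_random", "make_synthetic_connectome", "load_connectome",
    "save_graph", "graph_metrics",
]


@dataclass
class NetworkGraph:
    """A weighted/directed network with node labels and optional grouping.

    Parameters
    ----------
    weights : (n, n) ndarray
        Nonnegative weight matrix, ``weights[i, j]`` = influence of j on i.
    directed : bool
        If False the matrix must be symmetric.
    weighted : bool
        If False all entries are 0 or 1; if True entries lie in [0, 1].
    node_labels : list of str
        Unique label per node.
    region_of_node : dict, optional
        Node index -> anatomical/region label.
    module_of_node : dict, optional
        Node index -> planted module id (synthetic connectomes only);
        used to test community recovery.
    """

    weights: np.ndarray
    directed: bool = False
    weighted: bool = False
    node_labels: list[str] = field(default_factory=list)
    region_of_node: Optional[dict[int, str]] = None
    module_of_node: Optional[dict[int, int]] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(self.weights.shape[0])]
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed")
        if self.weighted:
            if w.max(initial=0.0) > 1.0 + 1e-12:
                raise ValueError("weighted graphs must have weights in [0, 1]")
        else:
            if not np.all(np.isin(w, (0.0, 1.0))):
                raise ValueError("unweighted graphs must be binary")
        if not self.directed and not np.allclose(w, w.T):
            raise ValueError("undirected graphs need a symmetric matrix")
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("one label per node required")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")

    # -- derived quantities --------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def in_degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    @property
    def out_degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)

    @property
    def in_strength(self) -> np.ndarray:
        """Row sums; equals the in-degree for binary graphs."""
        return self.weights.sum(axis=1)

    def skeleton(self) -> np.ndarray:
        """Binary undirected adjacency (max-symmetrized, binarized)."""
        a = (self.weights > 0) | (self.weights.T > 0)
        return a.astype(float)

    def to_networkx(self, skeleton: bool = False) -> nx.Graph:
        if skeleton or not self.directed:
            return nx.from_numpy_array(self.skeleton() if skeleton
                                       else self.weights)
        # row=target: transpose so nx edge (u, v) means u -> v influence
        return nx.from_numpy_array(self.weights.T, create_using=nx.DiGraph)


@dataclass
class GraphMetrics:
    """Summary metrics of a (binarized, undirected) graph."""

    avg_path_length: float
    clustering_coeff: float
    small_world_omega: float
    mean_degree: float
    powerlaw_exponent: float


# ---------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------

_MAX_REGEN = 20


def _regenerate_connected(build, seed: int) -> nx.Graph:
    """Call ``build(seed)`` and retry with incremented seed until connected."""
    for attempt in range(_MAX_REGEN):
        g = build(seed + attempt)
        if nx.is_connected(g):
            if attempt:
                logger.info("regenerated disconnected graph %d time(s)", attempt)
            return g
    raise RuntimeError(f"could not generate a connected graph in {_MAX_REGEN} tries")


def make_small_world(n: int, mean_degree: int, rewire_p: float,
                     seed: int = 0) -> NetworkGraph:
    """Watts–Strogatz small-world graph (binary, undirected).

    Each node starts on a ring connected to its ``mean_degree`` nearest
    neighbours; each edge is rewired with probability ``rewire_p``.
    Rewiring conserves the number of edges.
    """
    if not (n > mean_degree >= 2):
        raise ValueError("need n > mean_degree >= 2")
    if mean_degree % 2:
        raise ValueError("mean_degree must be even for a ring lattice")
    if not 0.0 <= rewire_p <= 1.0:
        raise ValueError("rewire_p must be a probability")
    g = _regenerate_connected(
        lambda s: nx.watts_strogatz_graph(n, mean_degree, rewire_p, seed=s), seed)
    return NetworkGraph(nx.to_numpy_array(g), directed=False, weighted=False)


def make_scale_free(n: int, m: int, seed: int = 0) -> NetworkGraph:
    """Barabási–Albert scale-free graph with attachment parameter ``m``."""
    if not n > m >= 1:
        raise ValueError("need n > m >= 1")
    g = _regenerate_connected(
        lambda s: nx.barabasi_albert_graph(n, m, seed=s), seed)
    return NetworkGraph(nx.to_numpy_array(g), directed=False, weighted=False)


def make_random(n: int, mean_degree: float, seed: int = 0) -> NetworkGraph:
    """Erdős–Rényi G(n, p) with p chosen to give the requested mean degree."""
    if not 0 < mean_degree <= n - 1:
        raise ValueError("need 0 < mean_degree <= n - 1")
    p = mean_degree / (n - 1)
    g = _regenerate_connected(lambda s: nx.gnp_random_graph(n, p, seed=s), seed)
    return NetworkGraph(nx.to_numpy_array(g), directed=False, weighted=False)


def make_synthetic_connectome(n_regions: int = 60, n_modules: int = 3,
                              intra_density: float = 0.5,
                              inter_density: float = 0.05,
                              weight_shape: float = 3.0, seed: int = 0,
                              module_strengths: Optional[np.ndarray] = None,
                              ) -> NetworkGraph:
    """Brain-like synthetic connectome: modular, weighted, directed,
    bilaterally mirrored.

    Two mirrored hemispheres of ``n_regions / 2`` nodes each carry
    ``n_modules`` planted modules; a module spans both hemispheres (its
    mirror halves are linked by dense homotopic, callosal-like edges).
    Edges are drawn independently with probability ``intra_density``
    within a module and ``inter_density`` between modules (within and
    across hemispheres alike), and the hemisphere-1 wiring is an exact
    mirror image of hemisphere 0.  Weights are drawn from a
    heavy-tailed Pareto distribution with tail index ``weight_shape``
    and rescaled to [0, 1].

    ``module_strengths`` (length ``n_modules``) optionally scales the
    *input* weights of each module's nodes (within-module edges and
    incoming cross-module edges alike), so that some modules are
    strongly and others weakly coupled into the network — a caricature
    of cortico-thalamic versus hindbrain circuits whose recruitment
    into global synchronization differs.
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even (two mirrored hemispheres)")
    for d in (intra_density, inter_density):
        if not 0.0 <= d <= 1.0:
            raise ValueError("densities must be probabilities")
    if intra_density <= inter_density:
        raise ValueError("need intra_density > inter_density")
    nh = n_regions // 2
    if nh % n_modules:
        raise ValueError("n_regions/2 must be divisible by n_modules")
    if module_strengths is None:
        module_strengths = np.ones(n_modules)
    module_strengths = np.asarray(module_strengths, dtype=float)
    if module_strengths.shape != (n_modules,):
        raise ValueError("module_strengths must have length n_modules")

    rng = np.random.default_rng(seed)
    per_mod = nh // n_modules
    mod_h = np.repeat(np.arange(n_modules), per_mod)          # within one hemisphere

    # draw one hemisphere-sized block plus one cross-hemisphere block,
    # then mirror both so the two hemispheres are exact copies; same
    # module => intra density, also across hemispheres (homotopic edges)
    same = mod_h[:, None] == mod_h[None, :]
    p_block = np.where(same, intra_density, inter_density)
    half = (rng.random((nh, nh)) < p_block).astype(float)
    np.fill_diagonal(half, 0.0)
    cross = (rng.random((nh, nh)) < p_block).astype(float)
    np.fill_diagonal(cross, 0.0)

    half *= rng.pareto(weight_shape, (nh, nh)) + 1.0
    cross *= rng.pareto(weight_shape, (nh, nh)) + 1.0

    w = np.zeros((n_regions, n_regions))
    w[:nh, :nh] = half
    w[nh:, nh:] = half          # mirrored hemisphere
    w[nh:, :nh] = cross
    w[:nh, nh:] = cross
    # row = target: scaling a row scales the module's input coupling
    row_scale = np.tile(module_strengths[mod_h], 2)
    w *= row_scale[:, None]
    w /= w.max()

    modules = {i: int(mod_h[i % nh]) for i in range(n_regions)}
    regions = {i: f"M{mod_h[i % nh]}-{'L' if i < nh else 'R'}"
               for i in range(n_regions)}
    labels = [f"{regions[i]}-{i % nh}" for i in range(n_regions)]
    return NetworkGraph(w, directed=True, weighted=True, node_labels=labels,
                        region_of_node=regions, module_of_node=modules)


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def load_connectome(path, fmt: str = "edge_list", binarize: bool = False,
                    symmetrize: bool = False) -> NetworkGraph:
    """Load a connectome from an edge list or a dense CSV matrix.

    Edge lists have one ``source target weight`` triple per line
    (whitespace- or comma-separated; weight optional, default 1); node
    labels are interned in order of first appearance.  Dense matrices
    use the row = target convention.  Weights are rescaled to [0, 1] by
    the maximum; ``binarize`` maps positive weights to 1; ``symmetrize``
    takes max(w_ij, w_ji) and yields an undirected graph.
    """
    path = Path(path)
    if fmt == "edge_list":
        labels: list[str] = []
        index: dict[str, int] = {}
        edges: list[tuple[int, int, float]] = []
        with open(path) as fh:
            for ln, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if ln == 0 and any(p.lower() in ("source", "src", "from")
                                   for p in parts[:1]):
                    continue  # header
                if len(parts) < 2:
                    raise ValueError(f"malformed edge-list line {ln + 1}")
                s, t = parts[0], parts[1]
                w = float(parts[2]) if len(parts) > 2 else 1.0
                for lab in (s, t):
                    if lab not in index:
                        index[lab] = len(labels)
                        labels.append(lab)
                edges.append((index[s], index[t], w))
        n = len(labels)
        weights = np.zeros((n, n))
        for s, t, w in edges:
            if w < 0:
                raise ValueError("negative weight in edge list")
            weights[t, s] = w       # source -> target enters row `target`
    elif fmt == "dense_matrix":
        weights = np.loadtxt(path, delimiter=",", ndmin=2)
        if weights.shape[0] != weights.shape[1]:
            raise ValueError("dense matrix must be square")
        if np.any(weights < 0):
            raise ValueError("negative weight in dense matrix")
        labels = [str(i) for i in range(weights.shape[0])]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if np.any(np.diag(weights) != 0):
        logger.warning("self-loops found in %s; zeroing the diagonal", path)
        np.fill_diagonal(weights, 0.0)
    directed = True
    if symmetrize:
        weights = np.maximum(weights, weights.T)
        directed = False
    if binarize:
        weights = (weights > 0).astype(float)
        return NetworkGraph(weights, directed=directed, weighted=False,
                            node_labels=labels)
    mx = weights.max()
    if mx > 0:
        weights = weights / mx
    return NetworkGraph(weights, directed=directed, weighted=True,
                        node_labels=labels)


def save_graph(g: NetworkGraph, path, fmt: str = "edge_list") -> None:
    """Write a graph as an edge list (``source target weight``) or dense CSV."""
    path = Path(path)
    if fmt == "dense_matrix":
        np.savetxt(path, g.weights, delimiter=",")
        return
    if fmt != "edge_list":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        tgt, src = np.nonzero(g.weights)
        for t, s in zip(tgt, src):
            if not g.directed and t > s:
                continue
            fh.write(f"{g.node_labels[s]} {g.node_labels[t]} "
                     f"{g.weights[t, s]:.10g}\n")


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def _largest_component(a: np.ndarray) -> np.ndarray:
    ncomp, lab = connected_components(csr_matrix(a), directed=False)
    if ncomp == 1:
        return a
    logger.info("graph disconnected; metrics computed on largest component")
    keep = lab == np.bincount(lab).argmax()
    return a[np.ix_(keep, keep)]


def _avg_path_length(a: np.ndarray) -> float:
    d = shortest_path(csr_matrix(a), method="D", unweighted=True)
    n = a.shape[0]
    if n < 2:
        raise ValueError("path length needs at least two nodes")
    return float(d[np.isfinite(d) & (d > 0)].sum() / (n * (n - 1)))


def _clustering(a: np.ndarray) -> float:
    a = (a > 0).astype(float)
    k = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


@njit(cache=True)
def _rewire(n, eu, ev, adj, n_attempts, toward_lattice, seed):  # pragma: no cover
    """Degree-preserving double-edge swaps on an undirected edge list.

    ``toward_lattice`` accepts a swap only if it reduces the total ring
    distance of the two edges (latticization); otherwise every valid
    swap is accepted (randomization).
    """
    np.random.seed(seed)
    m = eu.shape[0]
    for _ in range(n_attempts):
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        a, b = eu[e1], ev[e1]
        c, d = eu[e2], ev[e2]
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        if toward_lattice:
            dab = min(abs(a - b), n - abs(a - b))
            dcd = min(abs(c - d), n - abs(c - d))
            dad = min(abs(a - d), n - abs(a - d))
            dcb = min(abs(c - b), n - abs(c - b))
            if dad + dcb >= dab + dcd:
                continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        ev[e1] = d
        eu[e2] = c
        ev[e2] = b
    return adj


def _reference_graph(a: np.ndarray, toward_lattice: bool, seed: int,
                     sweeps: int) -> np.ndarray:
    n = a.shape[0]
    iu, ju = np.nonzero(np.triu(a > 0, 1))
    adj = (a > 0).astype(np.uint8)
    out = _rewire(n, iu.astype(np.int64).copy(), ju.astype(np.int64).copy(),
                  adj.copy(), sweeps * len(iu), toward_lattice,
                  seed % 2**31)
    return out.astype(float)


def small_world_omega(a: np.ndarray, n_reference: int = 10, seed: int = 0,
                      lattice_sweeps: int = 4000,
                      random_sweeps: int = 10) -> float:
    """Small-world coefficient omega = L_rand / L − C / C_latt.

    ``L_rand`` is averaged over ``n_reference`` degree-preserving
    randomized references; ``C_latt`` comes from a degree-preserving
    latticized reference (edge swaps accepted only when they shorten
    ring distance, run to near-stall).  omega is ≈ −1 for a lattice,
    ≈ +1 for a random graph, and near 0 for a small world.
    """
    L = _avg_path_length(a)
    C = _clustering(a)
    l_rand = np.mean([
        _avg_path_length(_reference_graph(a, False, seed + i, random_sweeps))
        for i in range(n_reference)])
    c_latt = _clustering(_reference_graph(a, True, seed, lattice_sweeps))
    return float(np.clip(l_rand / L - C / c_latt, -1.0, 1.0))


def powerlaw_exponent(degrees: np.ndarray) -> float:
    """Least-squares slope of log10(count) vs log10(degree) over occupied
    degree bins.  A crude but standard summary of degree-distribution
    heavy-tailedness; negative for scale-free-like graphs."""
    degrees = np.asarray(degrees)
    degrees = degrees[degrees > 0]
    vals, counts = np.unique(degrees, return_counts=True)
    if len(vals) < 2:
        return float("nan")
    slope = np.polyfit(np.log10(vals), np.log10(counts), 1)[0]
    return float(slope)


def graph_metrics(g: NetworkGraph, n_reference: int = 10,
                  seed: int = 0) -> GraphMetrics:
    """Path length, clustering, small-world omega, mean degree, and
    power-law exponent of a graph.

    Directed/weighted graphs are analysed on their binarized undirected
    skeleton; disconnected graphs on their largest component.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    a = _largest_component(g.skeleton())
    deg = a.sum(axis=1)
    return GraphMetrics(
        avg_path_length=_avg_path_length(a),
        clustering_coeff=_clustering(a),
        small_world_omega=small_world_omega(a, n_reference=n_reference,
                                            seed=seed),
        mean_degree=float(deg.mean()),
        powerlaw_exponent=powerlaw_exponent(deg),
    )
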