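"""Weighted-graph efficiency and small-world metrics with null normalisation.

Shortest paths treat each kept edge as having length 1/weight (strong
connections are short).  Global efficiency is the mean inverse shortest-path
length over ordered node pairs; nodal efficiency is the same mean restricted
to one source node; local efficiency of a node is the global efficiency of
the subgraph induced by its neighbours (original weights, node itself
excluded).  The clustering coefficient and characteristic path length are
computed on the binarised topology.  Small-world normalisation divides the
observed global and local efficiency by their means over degree-preserving
null networks (topology rewired by double edge swaps, the original weight
multiset re-assigned at random), yielding lambda, gamma and
sigma = gamma / lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .netbuild import FCNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PathLengthMatrix",
    "NodalMetrics",
    "GlobalMetrics",
    "NullEnsembleSummary",
    "path_lengths",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "clustering_and_path",
    "compute_nodal_metrics",
    "degree_preserving_null",
    "smallworld_normalize",
    "small_world_metrics",
]


@dataclass
class PathLengthMatrix:
    """All-pairs weighted shortest-path lengths; +inf for unreachable pairs."""

    d: np.ndarray


@dataclass
class NodalMetrics:
    """Per-node network properties of one subject's functional network."""

    e_nodal: np.ndarray
    e_local: np.ndarray
    c_node: np.ndarray
    l_node: np.ndarray


@dataclass
class GlobalMetrics:
    e_glob: float
    e_loc: float
    cp: float
    lp: float
    gamma: float = np.nan
    lambda_: float = np.nan
    sigma: float = np.nan


@dataclass
class NullEnsembleSummary:
    n_nulls: int
    mean_e_glob: float
    mean_e_loc: float
    mean_cp: float
    mean_lp: float
    seed: int


def _as_weights(net) -> np.ndarray:
    return net.weights if isinstance(net, FCNetwork) else np.asarray(net, dtype=float)


def _length_graph(w: np.ndarray) -> csr_array:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return csr_array(lengths)


def path_lengths(net) -> PathLengthMatrix:
    """Dijkstra all-pairs shortest paths over edge lengths 1/weight."""
    w = _as_weights(net)
    d = shortest_path(_length_graph(w), method="D", directed=False)
    return PathLengthMatrix(d)


def _efficiency_from_d(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(net) -> float:
    """Mean inverse shortest-path length over all ordered node pairs
    (unreachable pairs contribute zero)."""
    return _efficiency_from_d(path_lengths(net).d)


def nodal_efficiency(net, i: int | None = None):
    """Mean inverse shortest-path length from node ``i`` to every other
    node; the full vector if ``i`` is None."""
    w = _as_weights(net)
    n = w.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    d = path_lengths(w).d
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    e = inv.sum(axis=1) / (n - 1)
    if i is None:
        return e
    if not 0 <= i < n:
        raise IndexError(f"node {i} out of range 0..{n - 1}")
    return float(e[i])


def local_efficiency(net) -> tuple[np.ndarray, float]:
    """Per-node local efficiency (global efficiency of the neighbour-induced
    subgraph, original weights, zero when fewer than two neighbours) and its
    mean over nodes."""
    w = _as_weights(net)
    n = w.shape[0]
    e_local = np.zeros(n)
    adj = w > 0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        e_local[i] = _efficiency_from_d(path_lengths(sub).d)
    return e_local, float(e_local.mean()) if n else 0.0


def clustering_and_path(net) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Binary clustering coefficient and characteristic path length.

    c_node[i] counts edges among i's neighbours over D_i(D_i-1)/2 (zero for
    degree < 2); l_node[i] is the mean hop-count distance to reachable
    nodes; lp averages hop distance over ordered reachable pairs.  The
    fraction of unreachable pairs, if any, is logged.
    """
    w = _as_weights(net)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    a = (w > 0).astype(float)
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0  # edges among neighbours
    with np.errstate(divide="ignore", invalid="ignore"):
        c_node = np.where(deg >= 2, triangles / (deg * (deg - 1) / 2.0), 0.0)
    d = shortest_path(csr_array(a), method="D", directed=False, unweighted=True)
    off = ~np.eye(n, dtype=bool)
    reach = off & np.isfinite(d)
    l_node = np.array(
        [d[i, reach[i]].mean() if reach[i].any() else 0.0 for i in range(n)]
    )
    n_unreach = int((off & ~reach).sum())
    if n_unreach:
        logger.info(
            "characteristic path length: %d of %d ordered pairs unreachable",
            n_unreach,
            n * (n - 1),
        )
    lp = float(d[reach].mean()) if reach.any() else np.inf
    cp = float(c_node.mean())
    return cp, lp, c_node, l_node


def compute_nodal_metrics(net) -> NodalMetrics:
    """All per-node metrics of one network in a single pass."""
    e_nodal = nodal_efficiency(net)
    e_local, _ = local_efficiency(net)
    _, _, c_node, l_node = clustering_and_path(net)
    return NodalMetrics(e_nodal, e_local, c_node, l_node)


def _global_summary(w: np.ndarray) -> tuple[float, float, float, float]:
    e_glob = global_efficiency(w)
    _, e_loc = local_efficiency(w)
    cp, lp, _, _ = clustering_and_path(w)
    return e_glob, e_loc, cp, lp


def degree_preserving_null(
    net, n_nulls: int = 100, seed: int = 0
) -> NullEnsembleSummary:
    """Mean metrics over random networks matched on degree sequence and
    weight multiset.

    Each null rewires the binary topology with 10x(edge count) attempted
    double edge swaps, then permutes the original weights onto the rewired
    edges.  Deterministic under ``seed``.
    """
    w = _as_weights(net)
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    edge_weights = w[iu][w[iu] > 0]
    m = edge_weights.size
    if m < 2:
        raise ValueError("need at least 2 edges to build a degree-preserving null")
    g = nx.from_numpy_array((w > 0).astype(int))
    rng = np.random.default_rng(seed)
    sums = np.zeros(4)
    for k in range(n_nulls):
        gk = g.copy()
        try:
            nx.double_edge_swap(
                gk, nswap=10 * m, max_tries=1000 * m, seed=int(rng.integers(2**31))
            )
        except nx.NetworkXAlgorithmError:
            pass  # swap budget exhausted; degree sequence still preserved
        null = np.zeros_like(w)
        perm = rng.permutation(edge_weights)
        for (i, j), wt in zip(gk.edges(), perm):
            null[i, j] = null[j, i] = wt
        sums += np.array(_global_summary(null))
    means = sums / n_nulls
    return NullEnsembleSummary(n_nulls, *means, seed=seed)


def smallworld_normalize(
    e_glob: float, e_loc: float, cp: float, lp: float, nulls: NullEnsembleSummary
) -> GlobalMetrics:
    """gamma = E_loc / <E_loc^rand>, lambda = E_glob / <E_glob^rand>,
    sigma = gamma / lambda."""
    if nulls.mean_e_glob <= 0 or nulls.mean_e_loc <= 0:
        raise ValueError("null ensemble means must be positive")
    gamma = e_loc / nulls.mean_e_loc
    lambda_ = e_glob / nulls.mean_e_glob
    return GlobalMetrics(e_glob, e_loc, cp, lp, gamma, lambda_, gamma / lambda_)


def small_world_metrics(net, n_nulls: int = 100, seed: int = 0) -> GlobalMetrics:
    """Observed global metrics plus their small-world normalisation against
    ``n_nulls`` degree-preserving random networks."""
    w = _as_weights(net)
    e_glob, e_loc, cp, lp = _global_summary(w)
    nulls = degree_preserving_null(w, n_nulls=n_nulls, seed=seed)
    return smallworld_normalize(e_glob, e_loc, cp, lp, nulls)
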