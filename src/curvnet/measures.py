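"""Local and global graph-theoretical measures on weighted connectomes.

Edge weights are streamline counts, so stronger connections are shorter:
all path-based measures run on the length matrix d_ij = 1/w_ij.  Global
path measures additionally rescale weights by the subject's maximum
weight first (so lengths are >= 1, efficiency lands in [0, 1], and a
subject-level global scale factor — a nuisance in count data — drops
out).  Small-worldness is referenced to degree-preserving rewired
surrogates in which weights travel with their edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph

from curvnet.io import Connectome, Parcellation, ValidationError

logger = logging.getLogger("curvnet")

#: relative tolerance for treating two path lengths as tied
TIE_RTOL = 1e-12


class DegenerateGraphError(ValueError):
    """Raised when a graph has too few edges for the requested measure."""


@dataclass(frozen=True)
class DistanceGraph:
    """Length-matrix view of a connectome: d_ij = 1/w_ij, inf if absent."""

    parcellation: Parcellation
    distances: np.ndarray


@dataclass(frozen=True)
class GlobalMeasures:
    density: float
    diameter: float
    global_efficiency: float
    characteristic_path_length: float
    small_worldness: float
    clustering_mean: float
    disconnected: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "density": self.density,
            "diameter": self.diameter,
            "global_efficiency": self.global_efficiency,
            "characteristic_path_length": self.characteristic_path_length,
            "small_worldness": self.small_worldness,
            "clustering_mean": self.clustering_mean,
        }


def weight_to_distance(connectome: Connectome) -> DistanceGraph:
    """Map weights to lengths: d = 1/w on edges, +inf for absent pairs."""
    W = connectome.weights
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    return DistanceGraph(parcellation=connectome.parcellation, distances=D)


def _length_csr(distances: np.ndarray) -> csr_matrix:
    D = np.array(distances, copy=True)
    np.fill_diagonal(D, 0.0)
    finite = np.isfinite(D) & (D > 0)
    return csr_matrix((D[finite], np.nonzero(finite)), shape=D.shape)


def shortest_paths(distance_graph: DistanceGraph) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs geodesic lengths and shortest-path counts.

    Returns ``(geodesics, counts)``; unreachable pairs get ``inf`` length
    and count 0.  Ties in length are recognised with relative tolerance
    ``TIE_RTOL``, so equally long alternative routes are all counted.
    """
    D = distance_graph.distances
    n = D.shape[0]
    graph = _length_csr(D)
    geo = csgraph.dijkstra(graph, directed=False)
    counts = np.zeros((n, n))
    # count by relaxing nodes in order of distance from each source
    nbrs = [np.nonzero(np.isfinite(D[v]) & (D[v] > 0))[0] for v in range(n)]
    for s in range(n):
        dist = geo[s]
        order = np.argsort(dist)
        sigma = np.zeros(n)
        sigma[s] = 1.0
        for v in order:
            if not np.isfinite(dist[v]) or v == s:
                continue
            for u in nbrs[v]:
                target = dist[u] + D[u, v]
                if abs(target - dist[v]) <= TIE_RTOL * max(1.0, abs(dist[v])):
                    sigma[v] += sigma[u]
        counts[s] = sigma
        counts[s, s] = 1.0
    counts[~np.isfinite(geo)] = 0.0
    return geo, counts


def node_strength(connectome: Connectome) -> np.ndarray:
    """Strength s_i = sum_j w_ij (total weight incident to each node)."""
    return connectome.weights.sum(axis=1)


def _to_nx(connectome: Connectome) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(connectome.n_nodes))
    for i, j, w in connectome.edge_list():
        G.add_edge(i, j, weight=w, length=1.0 / w)
    return G


def betweenness_centrality(connectome: Connectome, normalized: bool = False) -> np.ndarray:
    """Betweenness on 1/w geodesics (Brandes accumulation).

    Unnormalized values count source-target pairs once; the normalized
    variant divides by (N-1)(N-2)/2.
    """
    G = _to_nx(connectome)
    bc = nx.betweenness_centrality(G, weight="length", normalized=normalized)
    return np.array([bc[i] for i in range(connectome.n_nodes)])


def clustering_coefficient(connectome: Connectome) -> np.ndarray:
    """Weighted clustering (Onnela geometric-mean form, weights / max w).

    Nodes with fewer than two neighbours score 0; values lie in [0, 1]
    and reduce to the binary coefficient on uniform weights.
    """
    if connectome.n_edges == 0:
        return np.zeros(connectome.n_nodes)
    G = _to_nx(connectome)
    cc = nx.clustering(G, weight="weight")
    return np.array([cc[i] for i in range(connectome.n_nodes)])


def rewired_null(
    connectome: Connectome, n_swaps: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> Connectome:
    """Degree-preserving rewired surrogate (Maslov-Sneppen double edge swaps).

    Each successful swap replaces edges (a,b),(c,d) with (a,d),(c,b);
    weights travel with their original edge, so both the degree sequence
    and the edge-weight multiset are preserved exactly.  ``n_swaps``
    counts attempts (default 10 x n_edges).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = connectome.edge_list()
    E = len(edges)
    if E < 2:
        logger.warning("rewired_null: fewer than 2 edges, returning input unchanged")
        return connectome
    if n_swaps is None:
        n_swaps = 10 * E
    present = {(i, j) for i, j, _ in edges}
    present |= {(j, i) for i, j in present}
    ea = [list(e) for e in edges]
    idx = rng.integers(0, E, size=2 * n_swaps)
    flips = rng.integers(0, 2, size=2 * n_swaps)
    for k in range(n_swaps):
        e1, e2 = idx[2 * k], idx[2 * k + 1]
        if e1 == e2:
            continue
        a, b, w1 = ea[e1]
        c, d, w2 = ea[e2]
        if flips[2 * k]:
            a, b = b, a
        if flips[2 * k + 1]:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if (a, d) in present or (c, b) in present:
            continue
        present -= {(a, b), (b, a), (c, d), (d, c)}
        present |= {(a, d), (d, a), (c, b), (b, c)}
        ea[e1] = [a, d, w1]
        ea[e2] = [c, b, w2]
    W = np.zeros_like(connectome.weights)
    for i, j, w in ea:
        W[i, j] = W[j, i] = w
    return Connectome(parcellation=connectome.parcellation, weights=W)


def _path_stats(W: np.ndarray) -> tuple[float, float, float, bool]:
    """(efficiency, char path length, diameter, disconnected) on max-scaled W."""
    n = W.shape[0]
    Wn = W / W.max()
    with np.errstate(divide="ignore"):
        L = np.where(Wn > 0, 1.0 / np.where(Wn > 0, Wn, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    geo = csgraph.dijkstra(_length_csr(L), directed=False)
    off = ~np.eye(n, dtype=bool)
    d = geo[off]
    finite = np.isfinite(d)
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    efficiency = float(inv.mean())
    if not finite.any():
        raise DegenerateGraphError("degenerate graph: no reachable pairs")
    cpl = float(d[finite].mean())
    diameter = float(d[finite].max())
    return efficiency, cpl, diameter, bool((~finite).any())


def global_measures(
    connectome: Connectome,
    n_null: int = 100,
    swap_factor: int = 10,
    seed: int | np.random.Generator | None = None,
    binarize: bool = False,
) -> GlobalMeasures:
    """Whole-brain summary measures of one connectome.

    density      fraction of possible node pairs with a nonzero weight
    efficiency   mean over ordered pairs of 1/d (0 for unreachable pairs)
    cpl          mean geodesic length over reachable pairs (``disconnected``
                 is set instead of returning inf when pairs are unreachable)
    diameter     longest finite geodesic
    small-worldness  sigma = (C/C_rand) / (L/L_rand) against ``n_null``
                 rewired surrogates, ``swap_factor * n_edges`` swap
                 attempts each, seeded
    """
    W = connectome.weights.copy()
    if binarize:
        W = (W > 0).astype(float)
        connectome = Connectome(parcellation=connectome.parcellation, weights=W)
    n = connectome.n_nodes
    E = connectome.n_edges
    if E < 1:
        raise DegenerateGraphError("degenerate graph: no edges")
    density = 2.0 * E / (n * (n - 1))
    efficiency, cpl, diameter, disconnected = _path_stats(W)
    C = float(clustering_coefficient(connectome).mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c_rand, l_rand = [], []
    for _ in range(n_null):
        surro = rewired_null(connectome, n_swaps=swap_factor * E, seed=rng)
        c_rand.append(float(clustering_coefficient(surro).mean()))
        l_rand.append(_path_stats(surro.weights)[1])
    if n_null == 0:
        sigma = float("nan")
    else:
        cr, lr = float(np.mean(c_rand)), float(np.mean(l_rand))
        sigma = (C / cr) / (cpl / lr) if cr > 0 and lr > 0 and C > 0 else float("nan")
    return GlobalMeasures(
        density=density, diameter=diameter, global_efficiency=efficiency,
        characteristic_path_length=cpl, small_worldness=sigma,
        clustering_mean=C, disconnected=disconnected,
    )
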