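"""Ollivier-Ricci curvature of weighted connectomes.

Curvature is the package's direct robustness measure.  Each node i
carries a lazy random-walk probability measure m_i: mass ``idleness``
stays on i, the rest spreads over neighbours proportionally to edge
weight.  The curvature of an edge (i, j) compares the optimal-transport
cost between the endpoint measures with the edge length,

    kappa_ij = 1 - W1(m_i, m_j) / d(i, j),

so overlapping neighbourhoods (cheap transport) give positive curvature
(robustness) and tree-like neighbourhoods give negative curvature
(fragility).  The ground metric d is the hop distance by default, or
the 1/w geodesic.  W1 is computed exactly by linear programming; all
edge problems of one graph are stacked into a single block-diagonal LP,
after removing the shared mass min(m_i, m_j), which for a metric ground
cost can always be left in place by some optimal plan.

Node curvature is the strength-weighted mean of incident edge
curvatures; global curvature is the plain mean of node curvatures over
non-isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph

from curvnet._transport import transport_cost
from curvnet.io import Connectome, ValidationError
from curvnet.measures import weight_to_distance, _length_csr

#: numerical slack for probability-mass bookkeeping
MASS_TOL = 1e-12

DEFAULT_IDLENESS = 0.5
GROUND_METRICS = ("hop", "weighted")


@dataclass(frozen=True)
class NeighborMeasure:
    """Lazy random-walk measure anchored at one node."""

    anchor_node: int
    support: np.ndarray       # node indices carrying mass, anchor first
    masses: np.ndarray        # probabilities, same order as support
    idleness: float

    def __post_init__(self) -> None:
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValidationError("neighbour measure masses must sum to 1")


@dataclass(frozen=True)
class CurvatureResult:
    edge_curvatures: dict[tuple[int, int], float]
    node_curvatures: np.ndarray       # NaN for isolated nodes
    global_curvature: float
    params: dict = field(default_factory=dict)


def neighbor_measure(
    connectome: Connectome, node: int, idleness: float = DEFAULT_IDLENESS
) -> NeighborMeasure:
    """Measure with mass ``idleness`` at ``node`` and (1-idleness) w_ij/s_i at
    each neighbour j."""
    if not 0.0 <= idleness < 1.0:
        raise ValidationError(f"idleness must be in [0, 1), got {idleness}")
    w = connectome.weights[node]
    nbrs = np.nonzero(w > 0)[0]
    if nbrs.size == 0:
        raise ValidationError(f"node {node} has no incident edges")
    s = w[nbrs].sum()
    support = np.concatenate([[node], nbrs])
    masses = np.concatenate([[idleness], (1.0 - idleness) * w[nbrs] / s])
    return NeighborMeasure(anchor_node=node, support=support, masses=masses,
                           idleness=idleness)


def _transport_lp(cost: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Exact W1 for one transportation problem via HiGHS."""
    na, nb = cost.shape
    ii, jj = np.divmod(np.arange(na * nb), nb)
    rows = np.concatenate([ii, na + jj])
    cols = np.concatenate([np.arange(na * nb), np.arange(na * nb)])
    A = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(na + nb, na * nb))
    res = linprog(cost.ravel(), A_eq=A, b_eq=np.concatenate([a, b]),
                  method="highs")
    if res.status != 0:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return max(res.fun, 0.0)


def wasserstein1(
    mu: NeighborMeasure | tuple[np.ndarray, np.ndarray],
    nu: NeighborMeasure | tuple[np.ndarray, np.ndarray],
    ground_distances: np.ndarray,
) -> float:
    """Exact Wasserstein-1 distance between two discrete measures.

    ``mu`` and ``nu`` are NeighborMeasures or (support, masses) pairs;
    ``ground_distances`` is the full node-by-node metric.  Raises if any
    pair of support points with mass has infinite ground distance.
    """
    sa, ma = (mu.support, mu.masses) if isinstance(mu, NeighborMeasure) else mu
    sb, mb = (nu.support, nu.masses) if isinstance(nu, NeighborMeasure) else nu
    ma, mb = np.asarray(ma, float), np.asarray(mb, float)
    if abs(ma.sum() - mb.sum()) > 1e-9:
        raise ValidationError("measures must have equal total mass")
    cost = ground_distances[np.ix_(np.asarray(sa), np.asarray(sb))]
    if not np.isfinite(cost).all():
        raise ValidationError("supports disconnected: infinite ground distance")
    return _transport_lp(cost, ma, mb * (ma.sum() / mb.sum()))


def _ground_distances(connectome: Connectome, ground_metric: str) -> np.ndarray:
    if ground_metric == "hop":
        A = csr_matrix((connectome.weights > 0).astype(float))
        return csgraph.shortest_path(A, method="D", unweighted=True, directed=False)
    if ground_metric == "weighted":
        D = weight_to_distance(connectome).distances
        return csgraph.dijkstra(_length_csr(D), directed=False)
    raise ValidationError(f"ground_metric must be one of {GROUND_METRICS}")


def edge_curvature(
    connectome: Connectome, i: int, j: int,
    idleness: float = DEFAULT_IDLENESS, ground_metric: str = "hop",
) -> float:
    """Curvature of a single edge via the full (unreduced) transport LP.

    Reference path kept deliberately simple; `edge_curvatures` is the
    fast route for whole graphs.
    """
    if connectome.weights[i, j] <= 0:
        raise ValidationError(f"no edge between {i} and {j}")
    D = _ground_distances(connectome, ground_metric)
    w1 = wasserstein1(
        neighbor_measure(connectome, i, idleness),
        neighbor_measure(connectome, j, idleness), D,
    )
    return 1.0 - w1 / D[i, j]


def edge_curvatures(
    connectome: Connectome,
    idleness: float = DEFAULT_IDLENESS,
    ground_metric: str = "hop",
    solver: str = "simplex",
) -> dict[tuple[int, int], float]:
    """Curvature of every edge of a graph (exact optimal transport).

    For each edge the shared mass min(m_i, m_j) is subtracted first
    (valid for metric ground costs: some optimal plan leaves common mass
    in place), which typically shrinks each transport problem to the
    non-overlapping parts of the two neighbourhoods.  One- or zero-point
    residuals are solved in closed form; the rest go to the exact
    network-simplex solver (``solver='simplex'``, default) or are
    stacked into a single block-diagonal HiGHS LP (``solver='lp'``) —
    both exact, the LP being the slower reference route.
    """
    if solver not in ("simplex", "lp"):
        raise ValidationError("solver must be 'simplex' or 'lp'")
    n = connectome.n_nodes
    W = connectome.weights
    D = _ground_distances(connectome, ground_metric)
    s = W.sum(axis=1)
    # dense measure vectors, one per non-isolated node
    M = np.zeros((n, n))
    active = s > 0
    M[active] = (1.0 - idleness) * W[active] / s[active, None]
    M[np.arange(n)[active], np.arange(n)[active]] = idleness

    edges = [(i, j) for i, j, _ in connectome.edge_list()]
    kappa: dict[tuple[int, int], float] = {}
    blocks: list[tuple[tuple[int, int], np.ndarray, np.ndarray, np.ndarray]] = []
    for (i, j) in edges:
        mu, nu = M[i], M[j]
        common = np.minimum(mu, nu)
        a_full, b_full = mu - common, nu - common
        si = np.nonzero(a_full > MASS_TOL)[0]
        sj = np.nonzero(b_full > MASS_TOL)[0]
        if si.size == 0 or sj.size == 0:
            kappa[(i, j)] = 1.0
            continue
        a, b = a_full[si], b_full[sj]
        b *= a.sum() / b.sum()
        cost = D[np.ix_(si, sj)]
        if not np.isfinite(cost).all():
            raise ValidationError(
                f"edge ({i}, {j}): supports disconnected under {ground_metric} metric"
            )
        if si.size == 1:
            kappa[(i, j)] = 1.0 - float(cost[0] @ b) / D[i, j]
        elif sj.size == 1:
            kappa[(i, j)] = 1.0 - float(cost[:, 0] @ a) / D[i, j]
        elif solver == "simplex":
            w1 = transport_cost(cost, a, b)
            if np.isnan(w1):  # iteration guard tripped; exact LP fallback
                w1 = _transport_lp(cost, a, b)
            kappa[(i, j)] = 1.0 - w1 / D[i, j]
        else:
            blocks.append(((i, j), cost, a, b))

    if blocks:
        costs, rowidx, colidx, beq = [], [], [], []
        vo = ro = 0
        for _, cost, a, b in blocks:
            na, nb = cost.shape
            costs.append(cost.ravel())
            ii, jj = np.divmod(np.arange(na * nb), nb)
            v = vo + np.arange(na * nb)
            rowidx += [ro + ii, ro + na + jj]
            colidx += [v, v]
            beq += [a, b]
            vo += na * nb
            ro += na + nb
        A = csr_matrix(
            (np.ones(2 * vo), (np.concatenate(rowidx), np.concatenate(colidx))),
            shape=(ro, vo),
        )
        c = np.concatenate(costs)
        res = linprog(c, A_eq=A, b_eq=np.concatenate(beq), method="highs")
        if res.status != 0:
            raise RuntimeError(f"batched transport LP failed: {res.message}")
        vo = 0
        for (e, cost, a, b) in blocks:
            nv = cost.size
            w1 = max(float(c[vo:vo + nv] @ res.x[vo:vo + nv]), 0.0)
            kappa[e] = 1.0 - w1 / D[e]
            vo += nv
    return kappa


def node_curvature(
    connectome: Connectome,
    idleness: float = DEFAULT_IDLENESS,
    ground_metric: str = "hop",
    edge_kappa: dict[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """Strength-weighted mean of incident edge curvatures; NaN if isolated."""
    if edge_kappa is None:
        edge_kappa = edge_curvatures(connectome, idleness, ground_metric)
    n = connectome.n_nodes
    W = connectome.weights
    s = W.sum(axis=1)
    acc = np.zeros(n)
    for (i, j), k in edge_kappa.items():
        acc[i] += W[i, j] * k
        acc[j] += W[i, j] * k
    out = np.full(n, np.nan)
    nz = s > 0
    out[nz] = acc[nz] / s[nz]
    return out


def global_curvature(
    connectome: Connectome,
    idleness: float = DEFAULT_IDLENESS,
    ground_metric: str = "hop",
    weight_by_strength: bool = False,
    edge_kappa: dict[tuple[int, int], float] | None = None,
) -> float:
    """Whole-network curvature: mean node curvature over non-isolated nodes
    (optionally strength-weighted)."""
    if connectome.n_edges < 1:
        raise ValidationError("global curvature undefined for an edgeless graph")
    nk = node_curvature(connectome, idleness, ground_metric, edge_kappa)
    ok = ~np.isnan(nk)
    if weight_by_strength:
        s = connectome.weights.sum(axis=1)[ok]
        return float(np.average(nk[ok], weights=s))
    return float(nk[ok].mean())


def curvature_result(
    connectome: Connectome,
    idleness: float = DEFAULT_IDLENESS,
    ground_metric: str = "hop",
) -> CurvatureResult:
    """Edge, node and global curvature in one pass (one LP per graph)."""
    ek = edge_curvatures(connectome, idleness, ground_metric)
    nk = node_curvature(connectome, idleness, ground_metric, edge_kappa=ek)
    gk = global_curvature(connectome, idleness, ground_metric, edge_kappa=ek)
    return CurvatureResult(
        edge_curvatures=ek, node_curvatures=nk, global_curvature=gk,
        params={"idleness": idleness, "ground_metric": ground_metric},
    )
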