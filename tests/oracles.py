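"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library code paths they check: shortest
paths and betweenness come from exhaustive simple-path enumeration,
clustering from direct evaluation of the geometric-mean triangle
formula, Holm-Sidak from a literal transcription of the step-down
definition, and optimal transport from enumeration of the vertices of
the transportation polytope (spanning-tree bases).
"""

from itertools import combinations, permutations

import numpy as np

TIE_RTOL = 1e-12


def enumerate_paths(W, s, t):
    """All simple paths s -> t in the weighted graph, with 1/w lengths."""
    n = W.shape[0]
    out = []

    def extend(path, length):
        u = path[-1]
        if u == t:
            out.append((list(path), length))
            return
        for v in range(n):
            if W[u, v] > 0 and v not in path:
                path.append(v)
                extend(path, length + 1.0 / W[u, v])
                path.pop()

    extend([s], 0.0)
    return out


def brute_shortest_paths(W):
    """(geodesics, counts) by exhaustive enumeration; inf/0 if unreachable."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    C = np.zeros((n, n))
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(C, 1.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = enumerate_paths(W, s, t)
            if not paths:
                continue
            best = min(length for _, length in paths)
            D[s, t] = best
            C[s, t] = sum(
                1 for _, length in paths
                if abs(length - best) <= TIE_RTOL * max(1.0, best)
            )
    return D, C


def brute_betweenness(W, normalized=False):
    """Pair-dependency betweenness from enumerated shortest paths."""
    n = W.shape[0]
    b = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = enumerate_paths(W, s, t)
        if not paths:
            continue
        best = min(length for _, length in paths)
        shortest = [p for p, length in paths
                    if abs(length - best) <= TIE_RTOL * max(1.0, best)]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            b[v] += through / len(shortest)
    if normalized:
        b /= (n - 1) * (n - 2) / 2
    return b


def brute_clustering(W):
    """Onnela geometric-mean clustering, weights scaled by the global max."""
    n = W.shape[0]
    mx = W.max()
    if mx == 0:
        return np.zeros(n)
    Wh = W / mx
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(W[i] > 0)[0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j, h in combinations(nbrs, 2):
            s += (Wh[i, j] * Wh[i, h] * Wh[j, h]) ** (1.0 / 3.0)
        c[i] = 2.0 * s / (k * (k - 1))
    return c


def brute_holm_sidak(p_values, alpha):
    """Literal step-down definition: sorted p_(i) vs 1-(1-alpha)^(1/(m-i+1))."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    for rank, idx in enumerate(order):  # rank 0 is the smallest p
        threshold = 1.0 - (1.0 - alpha) ** (1.0 / (m - rank))
        if p[idx] <= threshold:
            reject[idx] = True
        else:
            break
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, 1.0 - (1.0 - p[idx]) ** (m - rank)))
        adjusted[idx] = running
    return reject, adjusted


def brute_wasserstein1(a, b, cost):
    """Exact W1 by enumerating transportation-polytope vertices.

    Every vertex of the polytope is supported on a spanning forest of
    the complete bipartite support graph, i.e. on at most na+nb-1 cells;
    enumerate all such cell subsets, solve the (unique) flows on each
    spanning tree, keep the feasible ones, and take the cheapest.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    cells = [(i, j) for i in range(na) for j in range(nb)]
    best = np.inf
    for subset in combinations(cells, na + nb - 1):
        X = _solve_tree_flows(subset, a, b, na, nb)
        if X is None:
            continue
        best = min(best, float((X * cost).sum()))
    return best


def _solve_tree_flows(subset, a, b, na, nb):
    X = np.zeros((na, nb))
    remaining = list(subset)
    ra, rb = a.copy(), b.copy()
    active = set(subset)
    progress = True
    while remaining and progress:
        progress = False
        for cell in list(remaining):
            i, j = cell
            row_alone = sum(1 for (ii, _) in active if ii == i) == 1
            col_alone = sum(1 for (_, jj) in active if jj == j) == 1
            if row_alone or col_alone:
                x = ra[i] if row_alone else rb[j]
                if x < -1e-12:
                    return None
                X[i, j] = x
                ra[i] -= x
                rb[j] -= x
                remaining.remove(cell)
                active.remove(cell)
                progress = True
    if remaining:  # subset contained a cycle: not a basis
        return None
    if (np.abs(ra) > 1e-9).any() or (np.abs(rb) > 1e-9).any():
        return None
    if (X < -1e-12).any():
        return None
    return X
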