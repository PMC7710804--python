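"""Exact transportation solver (network simplex on the bipartite tableau).

Solves min <C, X> s.t. X 1 = a, X' 1 = b, X >= 0 for small dense
problems — the per-edge Wasserstein-1 subproblems of the curvature
module.  The basis tree is kept as explicit adjacency lists, so dual
prices and the pivot cycle are found by tree traversal in
O(na + nb) per iteration; the entering arc uses Dantzig's most-negative
reduced cost rule.  Degeneracy (frequent on unit-weight graphs, where
many masses tie exactly) is handled by the classical supply
perturbation a_i += (i+1)*eps; the returned objective is evaluated from
the optimal dual prices against the *unperturbed* masses, which by
strong duality is exact for the original problem.  Returns NaN if the
iteration guard trips; callers then fall back to the LP route.

Compiled with numba; the pure-LP reference implementation lives in
``curvnet.curvature`` and is used as the oracle in tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_ITER = 20000


@njit(cache=True)
def transport_cost(C: np.ndarray, a0: np.ndarray, b0: np.ndarray) -> float:  # pragma: no cover
    na, nb = C.shape
    total = 0.0
    for i in range(na):
        total += a0[i]
    eps = 1e-13 * total
    a = a0.copy()
    b = b0.copy()
    extra = 0.0
    for i in range(na):
        a[i] += eps * (i + 1)
        extra += eps * (i + 1)
    b[nb - 1] += extra

    # tree nodes: rows 0..na-1, cols na..na+nb-1
    nn = na + nb
    X = np.zeros((na, nb))
    # adjacency lists of the basis tree (a row can pair with at most nb
    # cols and vice versa)
    row_adj = np.full((na, nb), -1, np.int64)
    row_deg = np.zeros(na, np.int64)
    col_adj = np.full((nb, na), -1, np.int64)
    col_deg = np.zeros(nb, np.int64)

    # northwest-corner initial basic feasible solution
    aa = a.copy()
    bb = b.copy()
    i = 0
    j = 0
    while True:
        m = aa[i] if aa[i] < bb[j] else bb[j]
        X[i, j] = m
        row_adj[i, row_deg[i]] = j
        row_deg[i] += 1
        col_adj[j, col_deg[j]] = i
        col_deg[j] += 1
        aa[i] -= m
        bb[j] -= m
        if i == na - 1 and j == nb - 1:
            break
        if i < na - 1 and (aa[i] <= bb[j] or j == nb - 1):
            i += 1
        else:
            j += 1

    u = np.empty(na)
    v = np.empty(nb)
    stack = np.empty(nn, np.int64)
    parent_row = np.empty(na, np.int64)   # col that discovered this row
    parent_col = np.empty(nb, np.int64)   # row that discovered this col
    cyc_i = np.empty(2 * nn, np.int64)
    cyc_j = np.empty(2 * nn, np.int64)

    cost_scale = 1e-11 * (np.abs(C).max() + 1.0)
    for _ in range(_MAX_ITER):
        # dual prices by traversing the basis tree from row 0
        u[0] = 0.0
        top = 0
        stack[top] = 0  # encode rows as k, cols as na + j
        top += 1
        parent_row[:] = -2
        parent_col[:] = -2
        parent_row[0] = -1
        while top > 0:
            top -= 1
            node = stack[top]
            if node < na:
                r = node
                for t in range(row_deg[r]):
                    c = row_adj[r, t]
                    if parent_col[c] == -2:
                        parent_col[c] = r
                        v[c] = C[r, c] - u[r]
                        stack[top] = na + c
                        top += 1
            else:
                c = node - na
                for t in range(col_deg[c]):
                    r = col_adj[c, t]
                    if parent_row[r] == -2:
                        parent_row[r] = c
                        u[r] = C[r, c] - v[c]
                        stack[top] = r
                        top += 1
        # entering arc: most negative reduced cost
        best = -cost_scale
        bi = -1
        bj = -1
        for r in range(na):
            ur = u[r]
            for c in range(nb):
                red = C[r, c] - ur - v[c]
                if red < best:
                    best = red
                    bi = r
                    bj = c
        if bi < 0:
            out = 0.0
            for r in range(na):
                out += u[r] * a0[r]
            for c in range(nb):
                out += v[c] * b0[c]
            return out if out > 0.0 else 0.0
        # tree path from row bi to col bj (BFS with parent pointers)
        parent_row[:] = -2
        parent_col[:] = -2
        parent_row[bi] = -1
        top = 0
        stack[top] = bi
        top += 1
        while top > 0:
            top -= 1
            node = stack[top]
            if node < na:
                r = node
                for t in range(row_deg[r]):
                    c = row_adj[r, t]
                    if parent_col[c] == -2:
                        parent_col[c] = r
                        if c == bj:
                            top = 0
                            break
                        stack[top] = na + c
                        top += 1
            else:
                c = node - na
                for t in range(col_deg[c]):
                    r = col_adj[c, t]
                    if parent_row[r] == -2:
                        parent_row[r] = c
                        stack[top] = r
                        top += 1
        # cycle cells: entering (+), then path cells from col bj back to
        # row bi, alternating (-, +, -, ...)
        ncyc = 0
        cyc_i[ncyc] = bi
        cyc_j[ncyc] = bj
        ncyc += 1
        c = bj
        while True:
            r = parent_col[c]
            cyc_i[ncyc] = r
            cyc_j[ncyc] = c
            ncyc += 1
            if r == bi:
                break
            c = parent_row[r]
            cyc_i[ncyc] = r
            cyc_j[ncyc] = c
            ncyc += 1
        theta = np.inf
        li = -1
        lj = -1
        for k in range(1, ncyc, 2):
            x = X[cyc_i[k], cyc_j[k]]
            if x < theta:
                theta = x
                li = cyc_i[k]
                lj = cyc_j[k]
        for k in range(ncyc):
            if k % 2 == 0:
                X[cyc_i[k], cyc_j[k]] += theta
            else:
                X[cyc_i[k], cyc_j[k]] -= theta
        # pivot: entering joins the tree, leaving drops out
        X[bi, bj] = theta
        X[li, lj] = 0.0
        row_adj[bi, row_deg[bi]] = bj
        row_deg[bi] += 1
        col_adj[bj, col_deg[bj]] = bi
        col_deg[bj] += 1
        for t in range(row_deg[li]):
            if row_adj[li, t] == lj:
                row_adj[li, t] = row_adj[li, row_deg[li] - 1]
                row_deg[li] -= 1
                break
        for t in range(col_deg[lj]):
            if col_adj[lj, t] == li:
                col_adj[lj, t] = col_adj[lj, col_deg[lj] - 1]
                col_deg[lj] -= 1
                break
    return np.nan
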