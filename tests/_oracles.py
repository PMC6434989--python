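"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own clustering/statistics code
paths: the flood fill below works on plain Python sets with an explicit
neighbour definition, so agreement with the package is a genuine
two-route check.
"""

from __future__ import annotations

import numpy as np


def brute_force_clusters(t_map, neighbor_sets, t_th, min_size):
    """All signed supra-threshold connected components by BFS.

    ``neighbor_sets`` maps electrode index -> set of adjacent electrode
    indices.  Connectivity: same time & adjacent electrodes, or same
    electrode & adjacent times.  Returns a list of (frozenset of (e, t),
    sign, mass) tuples for components of at least ``min_size`` members.
    """
    t_map = np.asarray(t_map, dtype=float)
    n_el, n_ti = t_map.shape
    out = []
    for sign in (+1, -1):
        nodes = {
            (e, t)
            for e in range(n_el)
            for t in range(n_ti)
            if sign * t_map[e, t] > t_th
        }
        remaining = set(nodes)
        while remaining:
            start = remaining.pop()
            comp = {start}
            frontier = [start]
            while frontier:
                e, t = frontier.pop()
                cands = [(e, t - 1), (e, t + 1)] + [(e2, t) for e2 in neighbor_sets[e]]
                for cand in cands:
                    if cand in remaining:
                        remaining.discard(cand)
                        comp.add(cand)
                        frontier.append(cand)
            if len(comp) >= min_size:
                mass = float(sum(t_map[e, t] for e, t in comp))
                out.append((frozenset(comp), sign, mass))
    return out


def neighbor_sets_from_graph(adj, electrode_order):
    pos = {e: i for i, e in enumerate(electrode_order)}
    return {
        pos[e]: {pos[n] for n in adj.graph.neighbors(e)}
        for e in electrode_order
    }


def ols_fit(X, y):
    """Closed-form OLS estimates and standard errors (normal equations)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    return beta, se
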