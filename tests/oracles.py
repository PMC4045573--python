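"""Independent reference implementations used only to check the package.

Everything here is deliberately written along a different route from the
production code: dense pseudoinverse instead of reduced sparse solves,
explicit path enumeration instead of dependency accumulation, exhaustive
diode-state enumeration instead of relaxation.
"""

from __future__ import annotations

from itertools import combinations, product

import networkx as nx
import numpy as np


def pinv_potentials(net, source, target):
    """Pair potentials from the dense Moore-Penrose pseudoinverse of L."""
    nodes = net.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    L = nx.laplacian_matrix(net.graph, nodelist=nodes, weight="conductance").toarray()
    Lp = np.linalg.pinv(L.astype(float), rcond=1e-10)
    v = Lp[:, idx[str(source)]] - Lp[:, idx[str(target)]]
    v = v - v[idx[str(target)]]  # ground the target
    return {n: float(v[idx[n]]) for n in nodes}


def pinv_current_flow_centrality(net):
    """Brute-force C: explicit pair loop over pseudoinverse potentials.

    Endpoints carry the injected unit current; interior nodes half the sum
    of absolute incident currents.
    """
    nodes = net.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    L = nx.laplacian_matrix(net.graph, nodelist=nodes, weight="conductance").toarray()
    Lp = np.linalg.pinv(L.astype(float), rcond=1e-10)
    edges = net.edges()
    thr = {n: 0.0 for n in nodes}
    M = 0
    for s, t in combinations(nodes, 2):
        V = Lp[:, idx[s]] - Lp[:, idx[t]]
        M += 1
        for n in nodes:
            if n in (s, t):
                thr[n] += 1.0
            else:
                total = sum(
                    c * abs(V[idx[u]] - V[idx[v]])
                    for u, v, c in edges
                    if n in (u, v)
                )
                thr[n] += 0.5 * total
    return {n: thr[n] / M for n in nodes}


def bfs_betweenness(net):
    """Betweenness by explicit enumeration of every shortest path."""
    g = net.graph
    nodes = net.nodes
    n = len(nodes)
    score = {x: 0.0 for x in nodes}
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for x in path[1:-1]:
                score[x] += 1.0 / len(paths)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2.0
        score = {x: v / norm for x, v in score.items()}
    return score


def diode_state_solve(net, source, ground_conductance=1.0, injected=1.0):
    """Directed solve by enumerating every diode on/off pattern.

    Feasible for a dozen arcs or so.  Returns the voltages of the unique
    consistent pattern (active arcs must run downhill, blocked arcs uphill).
    """
    nodes = net.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    arcs = net.edges()
    b = np.zeros(n)
    b[idx[str(source)]] = injected
    for pattern in product((0, 1), repeat=len(arcs)):
        A = np.eye(n) * ground_conductance
        for on, (u, v, c) in zip(pattern, arcs):
            if on:
                i, j = idx[u], idx[v]
                A[i, i] += c
                A[j, j] += c
                A[i, j] -= c
                A[j, i] -= c
        V = np.linalg.solve(A, b)
        ok = True
        for on, (u, v, c) in zip(pattern, arcs):
            d = V[idx[u]] - V[idx[v]]
            if (on and d < -1e-12) or (not on and d > 1e-12):
                ok = False
                break
        if ok:
            return {nodes[i]: float(V[i]) for i in range(n)}
    raise AssertionError("no consistent diode pattern found")


def mle_powerlaw_exponent(degrees, lo, hi, grid=None):
    """Maximum-likelihood exponent of a truncated discrete power law."""
    ks = np.asarray([k for k in degrees if lo <= k <= hi], dtype=float)
    support = np.arange(lo, hi + 1, dtype=float)
    if grid is None:
        grid = np.linspace(1.05, 4.5, 1000)
    best, best_ll = grid[0], -np.inf
    for a in grid:
        ll = -a * np.log(ks).sum() - len(ks) * np.log((support ** (-a)).sum())
        if ll > best_ll:
            best_ll, best = ll, a
    return float(best)


def random_connected_graph(rng, n_max=8, weighted=False):
    """Small random connected graph for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if nx.is_connected(g):
            break
    edges = []
    for u, v in g.edges():
        c = float(rng.uniform(0.5, 2.0)) if weighted else 1.0
        edges.append((u, v, c))
    from keynodes import ConductanceNetwork

    return ConductanceNetwork.from_edges(edges)
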