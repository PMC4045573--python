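"""Current-flow centrality, accumulated edge flows and a betweenness baseline.

The current-flow centrality ``C`` of a node is the current passing through
it when a unit current is injected at a source node and withdrawn at a
target node, averaged over all source-target configurations.  For a node
other than the two endpoints this is half the sum of the absolute currents
on its incident edges (current in equals current out); the endpoints
themselves are assigned the injected current.  For directed networks the
target is the universal sink: every node is taken as the source in turn and
the node's ground branch counts among its incident edges.

Unlike shortest-path betweenness, ``C`` credits *all* paths with current in
proportion to their conductance, so a node can be central without lying on
a single shortest path.

The same source-target sweep also yields the accumulated absolute edge
flows ``T`` (input to the imbalance index) and, per configuration, the
max-minus-median imbalance of each node's incident currents.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .circuit import EdgeFlowTable, GROUND, PotentialField, edge_currents, solve_directed, solve_undirected
from .errors import SolverError
from .graph_io import ConductanceNetwork, natural_key

__all__ = [
    "NodeScoreTable",
    "FlowProfile",
    "node_throughflow",
    "current_flow_centrality",
    "directed_current_flow_centrality",
    "accumulate_edge_flows",
    "shortest_path_betweenness",
    "flow_profile",
]

_PAIR_CHUNK = 256  # source-target configurations vectorized at a time


@dataclass
class NodeScoreTable:
    """Per-node scalar scores with the scoring scheme and sweep size."""

    scores: dict[str, float]
    scheme: str  # C_undirected | C_directed | D_index | betweenness
    pair_count: int

    def __getitem__(self, node) -> float:
        return self.scores[str(node)]

    def ranked(self) -> list[tuple[str, float]]:
        """Nodes sorted by descending score (ties in natural label order)."""
        return sorted(
            self.scores.items(), key=lambda kv: (-kv[1], natural_key(kv[0]))
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tscore\tscheme\trank\n")
            for rank, (node, score) in enumerate(self.ranked(), start=1):
                fh.write(f"{node}\t{score!r}\t{self.scheme}\t{rank}\n")


@dataclass
class FlowProfile:
    """Everything one full source-target sweep produces.

    ``centrality``: the C score table; ``accumulated``: absolute edge flows
    summed over all configurations (directed arc pairs merged);
    ``imbalance_raw``: per node, the max-minus-median of its incident
    absolute currents, summed over configurations (unnormalized).
    """

    centrality: NodeScoreTable
    accumulated: EdgeFlowTable
    imbalance_raw: dict[str, float]
    pair_count: int


def node_throughflow(
    net: ConductanceNetwork,
    flows: EdgeFlowTable,
    node,
    source,
    target,
    injected: float = 1.0,
) -> float:
    """Current through ``node`` in one source-target configuration.

    Interior nodes: half the sum of absolute incident currents (ground
    branch included for directed solves).  The source and target themselves
    carry the injected current by convention.
    """
    node, source, target = str(node), str(source), str(target)
    if not net.has_node(node):
        raise ValueError(f"node {node!r} is not in the network")
    if node in (source, target):
        return injected
    total = sum(abs(f) for f in flows.incident(node))
    total += abs(flows.ground_flows.get(node, 0.0))
    return 0.5 * total


# -- undirected sweep ---------------------------------------------------------


def _grounded_inverse(L: np.ndarray) -> np.ndarray:
    """Inverse of the Laplacian with node 0 grounded, embedded at full size."""
    m = L.shape[0]
    X = np.zeros((m, m))
    if m > 1:
        X[1:, 1:] = np.linalg.inv(L[1:, 1:])
    return X


def _incidence_padding(n_nodes: int, eu: np.ndarray, ev: np.ndarray):
    """Per-node incident-edge index matrix, padded with a sentinel column."""
    E = len(eu)
    lists: list[list[int]] = [[] for _ in range(n_nodes)]
    for j in range(E):
        lists[eu[j]].append(j)
        lists[ev[j]].append(j)
    maxd = max((len(l) for l in lists), default=0)
    pad = np.full((n_nodes, max(maxd, 1)), E, dtype=int)
    for i, l in enumerate(lists):
        pad[i, : len(l)] = l
    return pad, pad == E


def _sweep_component(g: nx.Graph, nodes: list[str], injected: float):
    """Vectorized all-pairs sweep on one connected component.

    Returns per-node throughflow sums, per-edge accumulated absolute flows
    (keyed by edge tuple), per-node summed max-minus-median imbalance, and
    the number of configurations.
    """
    m = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    L = nx.laplacian_matrix(g, nodelist=nodes, weight="conductance").toarray().astype(float)
    X = _grounded_inverse(L)
    edges = [(u, v, d["conductance"]) for u, v, d in g.edges(data=True)]
    eu = np.array([idx[u] for u, v, c in edges], dtype=int)
    ev = np.array([idx[v] for u, v, c in edges], dtype=int)
    ec = np.array([c for u, v, c in edges], dtype=float)
    pad, mask = _incidence_padding(m, eu, ev)

    pairs = np.array(list(combinations(range(m), 2)), dtype=int)
    thr = np.zeros(m)
    T = np.zeros(len(edges))
    d_raw = np.zeros(m)
    for a in range(0, len(pairs), _PAIR_CHUNK):
        P = pairs[a : a + _PAIR_CHUNK]
        ch = len(P)
        V = X[:, P[:, 0]] - X[:, P[:, 1]]  # potentials, target grounded
        F = np.abs(ec[:, None] * (V[eu, :] - V[ev, :])) * injected
        T += F.sum(axis=1)
        halves = np.zeros((m, ch))
        np.add.at(halves, eu, F)
        np.add.at(halves, ev, F)
        halves *= 0.5
        cols = np.arange(ch)
        halves[P[:, 0], cols] = injected
        halves[P[:, 1], cols] = injected
        thr += halves.sum(axis=1)
        if len(edges):
            Fp = np.vstack([F, np.zeros((1, ch))])
            A = np.where(mask[:, :, None], np.nan, Fp[pad, :])
            with np.errstate(all="ignore"):
                d = np.nanmax(A, axis=1) - np.nanmedian(A, axis=1)
            d_raw += np.nan_to_num(d).sum(axis=1)
    T_keyed = {(u, v): float(t) for (u, v, c), t in zip(edges, T)}
    return thr, T_keyed, d_raw, len(pairs)


def _undirected_profile(net: ConductanceNetwork, injected: float = 1.0) -> FlowProfile:
    g = net.graph
    all_nodes = net.nodes
    thr = {n: 0.0 for n in all_nodes}
    d_raw = {n: 0.0 for n in all_nodes}
    T: dict[tuple[str, str], float] = {(u, v): 0.0 for u, v, _ in net.edges()}
    M = 0
    for comp in nx.connected_components(g):
        comp_nodes = sorted(comp, key=natural_key)
        if len(comp_nodes) < 2:
            continue
        sub = g.subgraph(comp_nodes)
        c_thr, c_T, c_d, c_M = _sweep_component(sub, comp_nodes, injected)
        M += c_M
        for i, n in enumerate(comp_nodes):
            thr[n] += float(c_thr[i])
            d_raw[n] += float(c_d[i])
        for (u, v), t in c_T.items():
            key = (u, v) if (u, v) in T else (v, u)
            T[key] += t
    if M == 0:
        raise SolverError("current-flow centrality needs at least one connected pair")
    C = NodeScoreTable(
        scores={n: thr[n] / M for n in all_nodes},
        scheme="C_undirected",
        pair_count=M,
    )
    acc = EdgeFlowTable(flows=T, mode="accumulated_absolute", configurations=M)
    return FlowProfile(centrality=C, accumulated=acc, imbalance_raw=d_raw, pair_count=M)


# -- directed sweep -----------------------------------------------------------


def _directed_profile(
    net: ConductanceNetwork,
    ground_conductance: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    damping: float = 0.5,
    injected: float = 1.0,
    include_ground_in_imbalance: bool = False,
) -> FlowProfile:
    nodes = net.nodes
    N = len(nodes)
    arcs = net.edges()
    # merged (undirected) edge keys for the accumulated table
    merged_keys: dict[frozenset, tuple[str, str]] = {}
    for u, v, _ in arcs:
        merged_keys.setdefault(frozenset((u, v)), (u, v))
    T = {key: 0.0 for key in merged_keys.values()}
    thr = {n: 0.0 for n in nodes}
    d_raw = {n: 0.0 for n in nodes}
    neighbors = {n: set(net.graph.predecessors(n)) | set(net.graph.successors(n)) for n in nodes}

    for s in nodes:
        try:
            pot = solve_directed(
                net,
                s,
                ground_conductance=ground_conductance,
                tol=tol,
                max_iter=max_iter,
                damping=damping,
                injected_current=injected,
            )
        except SolverError as exc:
            raise SolverError(f"directed solve failed for source {s!r}: {exc}") from exc
        flows = edge_currents(net, pot)
        merged_cfg: dict[frozenset, float] = {}
        for (u, v), f in flows.flows.items():
            merged_cfg[frozenset((u, v))] = merged_cfg.get(frozenset((u, v)), 0.0) + f
        for key, f in merged_cfg.items():
            T[merged_keys[key]] += f
        for n in nodes:
            thr[n] += node_throughflow(net, flows, n, s, GROUND, injected=injected)
            inc = [merged_cfg[frozenset((n, nb))] for nb in neighbors[n]]
            if include_ground_in_imbalance:
                inc.append(flows.ground_flows.get(n, 0.0))
            if len(inc) > 1:
                d_raw[n] += float(max(inc) - np.median(inc))
    C = NodeScoreTable(
        scores={n: thr[n] / N for n in nodes}, scheme="C_directed", pair_count=N
    )
    acc = EdgeFlowTable(flows=T, mode="accumulated_absolute", configurations=N)
    return FlowProfile(centrality=C, accumulated=acc, imbalance_raw=d_raw, pair_count=N)


# -- public operations --------------------------------------------------------


def flow_profile(
    net: ConductanceNetwork,
    *,
    injected: float = 1.0,
    ground_conductance: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    damping: float = 0.5,
    include_ground_in_imbalance: bool = False,
) -> FlowProfile:
    """Run the full source-target sweep once and return C, T and imbalance.

    ``ground_conductance``, ``tol``, ``max_iter``, ``damping`` and
    ``include_ground_in_imbalance`` only matter for directed networks.
    """
    if net.directed:
        return _directed_profile(
            net,
            ground_conductance=ground_conductance,
            tol=tol,
            max_iter=max_iter,
            damping=damping,
            injected=injected,
            include_ground_in_imbalance=include_ground_in_imbalance,
        )
    return _undirected_profile(net, injected=injected)


def current_flow_centrality(
    net: ConductanceNetwork, method: str = "direct", tol: float = 1e-10, max_iter: int = 100_000
) -> NodeScoreTable:
    """Current-flow centrality over all unordered source-target pairs.

    ``method="direct"`` uses one factorization of the grounded Laplacian per
    component; ``method="jacobi"`` re-solves every configuration iteratively
    (slow; kept for cross-validation of the linear solver).
    """
    if net.directed:
        raise SolverError("use directed_current_flow_centrality for directed networks")
    if net.number_of_nodes < 2:
        raise SolverError("current-flow centrality needs at least two nodes")
    if method == "direct":
        return _undirected_profile(net).centrality
    if method != "jacobi":
        raise ValueError(f"unknown method {method!r}")
    nodes = net.nodes
    thr = {n: 0.0 for n in nodes}
    M = 0
    for comp in nx.connected_components(net.graph):
        comp_nodes = sorted(comp, key=natural_key)
        for s, t in combinations(comp_nodes, 2):
            pot = solve_undirected(net, s, t, method="jacobi", tol=tol, max_iter=max_iter)
            flows = edge_currents(net, pot)
            M += 1
            for n in nodes:
                if n in comp:
                    thr[n] += node_throughflow(net, flows, n, s, t)
    if M == 0:
        raise SolverError("current-flow centrality needs at least one connected pair")
    return NodeScoreTable(
        scores={n: thr[n] / M for n in nodes}, scheme="C_undirected", pair_count=M
    )


def directed_current_flow_centrality(
    net: ConductanceNetwork,
    ground_conductance: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    damping: float = 0.5,
) -> NodeScoreTable:
    """Directed current-flow centrality: every node as source, sink = ground."""
    return _directed_profile(
        net,
        ground_conductance=ground_conductance,
        tol=tol,
        max_iter=max_iter,
        damping=damping,
    ).centrality


def accumulate_edge_flows(net: ConductanceNetwork, **kwargs) -> EdgeFlowTable:
    """Absolute edge currents summed over the full configuration sweep.

    For directed networks opposite arcs between the same node pair are
    merged by adding their accumulated currents.
    """
    return flow_profile(net, **kwargs).accumulated


def shortest_path_betweenness(net: ConductanceNetwork) -> NodeScoreTable:
    """Standard shortest-path betweenness, normalized by (N-1)(N-2)/2.

    Tied shortest paths split their contribution evenly.  Edge conductances
    are ignored: paths are counted on the unweighted topology.
    """
    g = net.graph
    n = net.number_of_nodes
    if n < 3:
        scores = {x: 0.0 for x in net.nodes}
    else:
        scores = {
            str(k): float(v)
            for k, v in nx.betweenness_centrality(g, normalized=True).items()
        }
    return NodeScoreTable(scores=scores, scheme="betweenness", pair_count=n * (n - 1) // 2)
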