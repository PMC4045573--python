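"""Circuit solvers: node potentials and edge currents.

Undirected networks map onto resistor networks: a unit current is injected
at a source node and withdrawn at a target node, and the node potentials
satisfy Kirchhoff's current law combined with Ohm's law, i.e. the graph
Laplacian system ``L V = e_s - e_t``.  The target is grounded (``V_t = 0``)
and the reduced system is solved either directly (sparse LU) or by Jacobi
iteration, in which each node's potential is repeatedly replaced by the
conductance-weighted average of its neighbours' potentials.

Directed networks map onto diode networks: every arc conducts only in its
own orientation, every node additionally hangs on a ground branch leading to
a universal sink at potential zero, and a unit current is injected at the
source.  The potentials are the fixed point of a damped relaxation in which
a node's potential is the conductance-weighted average of its *conducting*
neighbours and ground; an arc ``u -> v`` conducts only while ``V_u > V_v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError
from .graph_io import ConductanceNetwork

__all__ = [
    "GROUND",
    "PotentialField",
    "EdgeFlowTable",
    "solve_undirected",
    "solve_directed",
    "edge_currents",
]

#: Sentinel label for the universal sink in directed solves.
GROUND = "__GROUND__"


@dataclass
class PotentialField:
    """Node potentials for a single source/target (or source/ground) solve.

    ``voltages`` maps every network node to a potential (target resp. ground
    at zero).  ``ground_conductance`` is set only for directed solves, where
    every node carries a ground branch of that conductance.
    """

    voltages: dict[str, float]
    source: str
    target: str  # node label or GROUND
    injected_current: float = 1.0
    ground_conductance: float | None = None
    iterations: int = 0
    residual: float = 0.0

    def __getitem__(self, node) -> float:
        return self.voltages[str(node)]


@dataclass
class EdgeFlowTable:
    """Per-edge currents.

    ``signed_single_pair`` tables hold the signed current of one
    source-target configuration, oriented along the stored edge key (current
    from ``u`` to ``v`` is positive; querying the reversed key negates).
    ``accumulated_absolute`` tables hold absolute currents summed over all
    configurations and are orientation-free.
    """

    flows: dict[tuple[str, str], float]
    mode: str  # "signed_single_pair" | "accumulated_absolute"
    configurations: int = 1
    ground_flows: dict[str, float] = field(default_factory=dict)

    def flow(self, u, v) -> float:
        u, v = str(u), str(v)
        if (u, v) in self.flows:
            return self.flows[(u, v)]
        if (v, u) in self.flows:
            f = self.flows[(v, u)]
            return -f if self.mode == "signed_single_pair" else f
        raise KeyError(f"no edge ({u!r}, {v!r}) in flow table")

    def incident(self, node) -> list[float]:
        """Flows on the edges incident to ``node`` (as stored, no sign flip)."""
        node = str(node)
        return [f for (u, v), f in self.flows.items() if node in (u, v)]


# -- shared index plumbing ----------------------------------------------------


def _index(net: ConductanceNetwork):
    nodes = net.nodes
    return nodes, {n: i for i, n in enumerate(nodes)}


def _laplacian(net: ConductanceNetwork, nodes) -> sp.csr_array:
    g = net.graph.to_undirected(as_view=False) if net.directed else net.graph
    return sp.csr_array(
        nx.laplacian_matrix(g, nodelist=nodes, weight="conductance"), dtype=float
    )


import networkx as nx  # noqa: E402  (used by _laplacian)


# -- undirected solver --------------------------------------------------------


def solve_undirected(
    net: ConductanceNetwork,
    source,
    target,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 100_000,
    injected_current: float = 1.0,
) -> PotentialField:
    """Solve node potentials for a unit current from ``source`` to ``target``.

    The target node is grounded at potential zero.  ``method="direct"``
    solves the reduced Laplacian system sparsely; ``method="jacobi"``
    iterates conductance-weighted neighbour averages until both the largest
    potential update and the Kirchhoff residual fall below ``tol`` (times the
    injected current).
    """
    source, target = str(source), str(target)
    if net.directed:
        raise SolverError("solve_undirected requires an undirected network")
    for n in (source, target):
        if not net.has_node(n):
            raise SolverError(f"node {n!r} is not in the network")
    if source == target:
        raise SolverError("source and target must differ")
    g = net.graph
    if not nx.has_path(g, source, target):
        raise SolverError(
            f"source {source!r} and target {target!r} lie in different components"
        )
    nodes, idx = _index(net)
    n = len(nodes)
    L = _laplacian(net, nodes)
    b = np.zeros(n)
    b[idx[source]] = injected_current
    b[idx[target]] = -injected_current

    keep = np.arange(n) != idx[target]
    if method == "direct":
        V = np.zeros(n)
        Lr = L[keep][:, keep].tocsc()
        # target's component is the full graph here (checked above); nodes in
        # other components, if any, stay at zero potential and carry no flow.
        comp = nx.node_connected_component(g, target)
        if len(comp) < n:
            sub = np.array([idx[x] for x in comp if x != target])
            order = {j: k for k, j in enumerate(np.flatnonzero(keep))}
            rows = np.array([order[j] for j in sub])
            Ls = Lr[rows][:, rows].tocsc()
            V[sub] = spla.spsolve(Ls, b[sub])
        else:
            V[keep] = spla.spsolve(Lr, b[keep])
        iters = 1
    elif method == "jacobi":
        V = np.zeros(n)
        deg = L.diagonal()
        A = sp.csr_array(sp.diags(deg) - L)  # conductance adjacency
        t_i = idx[target]
        safe_deg = np.where(deg > 0, deg, 1.0)
        for iters in range(1, max_iter + 1):
            V_new = (A @ V + b) / safe_deg
            V_new[t_i] = 0.0
            delta = np.max(np.abs(V_new - V))
            V = V_new
            if delta < tol:
                resid = L @ V - b
                resid[t_i] = 0.0
                if np.max(np.abs(resid)) < tol * abs(injected_current):
                    break
        else:
            resid = L @ V - b
            resid[t_i] = 0.0
            raise SolverError(
                f"Jacobi did not converge in {max_iter} iterations "
                f"(residual {np.max(np.abs(resid)):.3e})"
            )
    else:
        raise ValueError(f"unknown method {method!r}; use 'direct' or 'jacobi'")

    resid = L @ V - b
    resid[idx[target]] = 0.0
    residual = float(np.max(np.abs(resid)))
    return PotentialField(
        voltages={nodes[i]: float(V[i]) for i in range(n)},
        source=source,
        target=target,
        injected_current=injected_current,
        iterations=iters,
        residual=residual,
    )


def edge_currents(net: ConductanceNetwork, potentials: PotentialField) -> EdgeFlowTable:
    """Ohm's law on every edge: ``I_uv = c_uv (V_u - V_v)``.

    For directed networks (potentials from :func:`solve_directed`) an arc
    carries current only in its own orientation: ``I_uv = max(0, c_uv (V_u -
    V_v))``.  Ground-branch currents are reported separately per node.
    """
    V = potentials.voltages
    if set(V) != set(net.graph.nodes):
        raise ValueError("potential field does not match the network's node set")
    flows: dict[tuple[str, str], float] = {}
    for u, v, c in net.edges():
        i = c * (V[u] - V[v])
        if net.directed:
            i = max(0.0, i)
        flows[(u, v)] = i
    ground = {}
    if net.directed and potentials.ground_conductance is not None:
        g0 = potentials.ground_conductance
        ground = {n: g0 * V[n] for n in V}
    return EdgeFlowTable(flows=flows, mode="signed_single_pair", ground_flows=ground)


# -- directed (diode) solver --------------------------------------------------


def solve_directed(
    net: ConductanceNetwork,
    source,
    ground_conductance: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    damping: float = 0.5,
    injected_current: float = 1.0,
) -> PotentialField:
    """Solve the diode network for a unit current from ``source`` to ground.

    Every node carries a ground branch of conductance ``ground_conductance``
    to the universal sink at potential zero.  An arc ``u -> v`` behaves as an
    ideal diode: it conducts with the edge's conductance while ``V_u > V_v``
    and blocks otherwise.  The damped Jacobi relaxation raises a node's
    potential when it receives more current than it sheds and lowers it in
    the opposite case, until Kirchhoff's law holds at every node within
    ``tol`` times the injected current.
    """
    source = str(source)
    if not net.directed:
        raise SolverError("solve_directed requires a directed network")
    if not net.has_node(source):
        raise SolverError(f"source {source!r} is not in the network")
    if not ground_conductance > 0:
        raise SolverError("ground_conductance must be positive")
    if not 0 < damping <= 1:
        raise ValueError("damping must lie in (0, 1]")

    nodes, idx = _index(net)
    n = len(nodes)
    arcs = [(idx[u], idx[v], c) for u, v, c in net.edges()]
    au = np.array([a[0] for a in arcs], dtype=int)
    av = np.array([a[1] for a in arcs], dtype=int)
    ac = np.array([a[2] for a in arcs], dtype=float)
    inj = np.zeros(n)
    inj[idx[source]] = injected_current

    V = np.zeros(n)
    g0 = ground_conductance
    for iters in range(1, max_iter + 1):
        active = V[au] > V[av]
        ca = ac * active
        num = inj.copy()
        den = np.full(n, g0)
        # conducting arc u->v couples u and v like a resistor
        np.add.at(num, au, ca * V[av])
        np.add.at(num, av, ca * V[au])
        np.add.at(den, au, ca)
        np.add.at(den, av, ca)
        V_new = (1.0 - damping) * V + damping * num / den
        # Kirchhoff residual at the *updated* potentials
        active = V_new[au] > V_new[av]
        flow = np.where(active, ac * (V_new[au] - V_new[av]), 0.0)
        resid = inj - g0 * V_new
        np.add.at(resid, au, -flow)
        np.add.at(resid, av, flow)
        V = V_new
        if np.max(np.abs(resid)) < tol * abs(injected_current):
            break
    else:
        raise SolverError(
            f"directed relaxation did not converge for source {source!r} in "
            f"{max_iter} iterations (residual {np.max(np.abs(resid)):.3e})"
        )

    return PotentialField(
        voltages={nodes[i]: float(V[i]) for i in range(n)},
        source=source,
        target=GROUND,
        injected_current=injected_current,
        ground_conductance=g0,
        iterations=iters,
        residual=float(np.max(np.abs(resid))),
    )
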