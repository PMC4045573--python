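"""Seeded generators for community networks with planted ground truth.

Three families:

* :func:`generate_two_group_toy` — two mirrored groups whose gateways are
  joined both directly and through a central connector node, so the
  connector sits at the topological centre yet lies on no shortest path
  (shortest-path betweenness scores it zero while current still flows
  through it).
* :func:`generate_planted_network` — dense random community blocks joined
  *only* through planted connectors: bridging nodes (community members with
  a fixed number of cross edges) and overlapping nodes (extra nodes with a
  fixed number of edges into each of two host communities).  An optional
  background cross-edge probability ``p_out`` can blur the planted
  structure; its default is 0 so that the planted connectors are exactly
  the network's connectors and the truth labels are meaningful.
* :func:`generate_lfr_like` — heterogeneous benchmark graphs with
  power-law degrees (exponent ``tau1``) and power-law community sizes
  (exponent ``tau2``); each node sends a fraction ``mu`` of its edge stubs
  outside its community, and stubs are matched rejecting self-loops and
  parallel edges.

All generators are driven by a single integer seed and are reproducible
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .errors import KeynodesError
from .graph_io import ConductanceNetwork

__all__ = [
    "PlantedTruth",
    "PlantedSpec",
    "LFRSpec",
    "generate_two_group_toy",
    "generate_planted_network",
    "generate_lfr_like",
]


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a generated network.

    ``membership`` maps each node to the tuple of community ids it belongs
    to (overlapping nodes list two).
    """

    membership: dict[str, tuple[int, ...]]
    overlapping: set[str] = field(default_factory=set)
    bridging: set[str] = field(default_factory=set)

    @property
    def connectors(self) -> set[str]:
        return self.overlapping | self.bridging

    def to_dict(self) -> dict:
        return {
            "membership": {n: list(c) for n, c in sorted(self.membership.items())},
            "overlapping": sorted(self.overlapping),
            "bridging": sorted(self.bridging),
        }


# -- two-group toy ------------------------------------------------------------


def generate_two_group_toy(
    group_size: int = 6, seed: int = 0
) -> tuple[ConductanceNetwork, PlantedTruth]:
    """Two mirrored groups joined through a central connector node.

    Each group holds a hub (adjacent to every group member), a gateway
    (adjacent to the hub and the two mid nodes) and a path of mid and
    peripheral nodes.  The two gateways are joined directly *and* through
    the connector node, so every shortest inter-group path skips the
    connector.  The construction is deterministic; ``seed`` is accepted for
    interface uniformity.

    With ``group_size=6`` the nodes are labeled 1-13 with the connector at
    7, gateways at 6 and 8, hubs at 5 and 13.
    """
    del seed  # deterministic construction
    k = int(group_size)
    if k < 3:
        raise ValueError("group_size must be at least 3")

    def group_edges(labels: dict[str, int]) -> list[tuple[int, int]]:
        hub, gw = labels["hub"], labels["gateway"]
        mids = labels["mids"]
        path = labels["path"]
        edges = [(hub, x) for x in labels["members"] if x != hub]
        edges += [(gw, m) for m in mids]
        edges += list(zip(path, path[1:]))
        return edges

    if k == 3:
        g1 = {"members": [1, 2, 3], "hub": 2, "gateway": 3, "mids": [1], "path": []}
    else:
        peripherals = list(range(1, k - 3))
        mid1, mid2, hub, gw = k - 3, k - 2, k - 1, k
        g1 = {
            "members": list(range(1, k + 1)),
            "hub": hub,
            "gateway": gw,
            "mids": [mid1, mid2],
            "path": [mid2] + peripherals + [mid1],
        }
    connector = k + 1
    # mirror labels: gateway -> k+2, mid1 -> k+3, peripherals, mid2 -> 2k, hub -> 2k+1
    if k == 3:
        mirror = {3: 5, 1: 6, 2: 7}
    else:
        mirror = {g1["gateway"]: k + 2, g1["mids"][0]: k + 3, g1["mids"][1]: 2 * k, g1["hub"]: 2 * k + 1}
        for i, p in enumerate(range(1, k - 3)):
            mirror[p] = k + 4 + i

    e1 = group_edges(g1)
    e2 = [(mirror[u], mirror[v]) for u, v in e1]
    gw1, gw2 = g1["gateway"], mirror[g1["gateway"]]
    edges = e1 + e2 + [(gw1, connector), (connector, gw2), (gw1, gw2)]
    net = ConductanceNetwork.from_edges(edges, directed=False)
    membership: dict[str, tuple[int, ...]] = {}
    for x in g1["members"]:
        membership[str(x)] = (0,)
        membership[str(mirror[x])] = (1,)
    membership[str(connector)] = (0, 1)
    truth = PlantedTruth(membership=membership, overlapping={str(connector)})
    return net, truth


# -- planted community blocks -------------------------------------------------


@dataclass
class PlantedSpec:
    """Parameters of the planted-connector generator (repository defaults).

    Four communities of 25 nodes, within-community edge probability 0.3, no
    background cross edges, two bridging nodes with two cross edges each and
    one overlapping node with four edges into each of its two host
    communities.
    """

    n_communities: int = 4
    community_sizes: tuple[int, ...] = (25, 25, 25, 25)
    p_in: float = 0.3
    p_out: float = 0.0
    n_bridging: int = 2
    bridging_out_degree: int = 2
    n_overlapping: int = 1
    overlap_degree_per_community: int = 4
    seed: int = 0

    def validate(self) -> None:
        if len(self.community_sizes) != self.n_communities:
            raise KeynodesError("community_sizes length must equal n_communities")
        if self.n_communities < 2:
            raise KeynodesError("need at least two communities")
        if any(s < 3 for s in self.community_sizes):
            raise KeynodesError("community sizes must be at least 3")
        if not (0 < self.p_in <= 1):
            raise KeynodesError("p_in must lie in (0, 1]")
        if not (0 <= self.p_out < 1):
            raise KeynodesError("p_out must lie in [0, 1)")
        if self.p_in <= self.p_out:
            raise KeynodesError("p_in must exceed p_out")
        if self.n_bridging < 0 or self.n_overlapping < 0:
            raise KeynodesError("planted counts must be non-negative")
        if self.n_bridging > sum(self.community_sizes):
            raise KeynodesError("more bridging nodes than nodes available")
        if self.n_bridging and self.bridging_out_degree < 1:
            raise KeynodesError("bridging_out_degree must be at least 1")
        if self.n_overlapping:
            if self.overlap_degree_per_community < 2:
                raise KeynodesError("overlap_degree_per_community must be at least 2")
            if self.overlap_degree_per_community > min(self.community_sizes):
                raise KeynodesError(
                    "overlap_degree_per_community exceeds the smallest community"
                )


def _planted_attempt(spec: PlantedSpec, rng: np.random.Generator):
    sizes = spec.community_sizes
    comms: list[list[int]] = []
    nid = 0
    g = nx.Graph()
    for s in sizes:
        block = list(range(nid, nid + s))
        nid += s
        comms.append(block)
        g.add_nodes_from(block)
        for u, v in combinations(block, 2):
            if rng.random() < spec.p_in:
                g.add_edge(u, v)
    if spec.p_out > 0:
        for a, b in combinations(range(len(comms)), 2):
            for u in comms[a]:
                for v in comms[b]:
                    if rng.random() < spec.p_out:
                        g.add_edge(u, v)
    bridging: list[int] = []
    for b in range(spec.n_bridging):
        c = b % len(comms)
        pool = [x for x in comms[c] if x not in bridging]
        node = int(rng.choice(pool))
        others = [x for k, block in enumerate(comms) if k != c for x in block]
        targets = rng.choice(others, size=spec.bridging_out_degree, replace=False)
        g.add_edges_from((node, int(t)) for t in targets)
        bridging.append(node)
    overlapping: list[int] = []
    hosts: dict[int, tuple[int, int]] = {}
    for _ in range(spec.n_overlapping):
        node = nid
        nid += 1
        g.add_node(node)
        ca, cb = rng.choice(len(comms), size=2, replace=False)
        for c in (int(ca), int(cb)):
            targets = rng.choice(
                comms[c], size=spec.overlap_degree_per_community, replace=False
            )
            g.add_edges_from((node, int(t)) for t in targets)
        overlapping.append(node)
        hosts[node] = (int(ca), int(cb))
    return g, comms, bridging, overlapping, hosts


def generate_planted_network(
    spec: PlantedSpec | None = None, **overrides
) -> tuple[ConductanceNetwork, PlantedTruth]:
    """Dense community blocks joined through planted connector nodes.

    Bridging nodes are ordinary community members given exactly
    ``bridging_out_degree`` uniform cross edges; overlapping nodes are
    additional nodes given ``overlap_degree_per_community`` edges into each
    of two host communities.  Cross-edge targets are resampled (still under
    the seed) until the network is connected, so the planted connectors are
    guaranteed to join all communities; generation fails if 200 attempts do
    not produce a connected network.
    """
    if spec is None:
        spec = PlantedSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a PlantedSpec or keyword overrides, not both")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    for _ in range(200):
        g, comms, bridging, overlapping, hosts = _planted_attempt(spec, rng)
        if nx.is_connected(g):
            break
    else:
        raise KeynodesError(
            "could not generate a connected planted network in 200 attempts; "
            "the spec plants too few connectors for its community count"
        )
    net = ConductanceNetwork(g)
    membership: dict[str, tuple[int, ...]] = {}
    for ci, block in enumerate(comms):
        for x in block:
            membership[str(x)] = (ci,)
    for node in overlapping:
        membership[str(node)] = hosts[node]
    truth = PlantedTruth(
        membership=membership,
        overlapping={str(x) for x in overlapping},
        bridging={str(x) for x in bridging},
    )
    return net, truth


# -- LFR-style benchmark ------------------------------------------------------


@dataclass
class LFRSpec:
    """Parameters of the LFR-style generator.

    ``tau1``/``tau2`` are the power-law exponents of the degree and
    community-size distributions; ``mu`` is the mixing fraction of each
    node's stubs sent outside its community.  Degrees are truncated to
    ``[min_degree, sqrt(n)]`` so small instances stay connected-ish; if
    ``avg_degree`` is given, ``min_degree`` is raised until the expected
    degree is closest to it.
    """

    n: int = 250
    tau1: float = 2.0
    tau2: float = 1.0
    mu: float = 0.1
    avg_degree: float | None = None
    min_degree: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n < 10:
            raise KeynodesError("n must be at least 10")
        if self.tau1 <= 1 or self.tau2 < 1:
            raise KeynodesError("need tau1 > 1 and tau2 >= 1")
        if not (0 <= self.mu < 1):
            raise KeynodesError("mu must lie in [0, 1)")
        if self.min_degree < 1:
            raise KeynodesError("min_degree must be at least 1")


def _powerlaw_choice(rng, lo: int, hi: int, exponent: float, size: int) -> np.ndarray:
    support = np.arange(lo, hi + 1)
    w = support.astype(float) ** (-exponent)
    w /= w.sum()
    return rng.choice(support, size=size, p=w)


def generate_lfr_like(
    spec: LFRSpec | None = None, **overrides
) -> tuple[ConductanceNetwork, PlantedTruth]:
    """Benchmark graph with power-law degrees and community sizes.

    Stub matching rejects self-loops and parallel edges with bounded
    retries; a handful of unmatched stubs may be dropped, so realized
    degrees can fall slightly short of the sampled sequence.  Truth marks
    every node with at least one inter-community edge as bridging; no
    overlapping membership is planted.
    """
    if spec is None:
        spec = LFRSpec(**overrides)
    elif overrides:
        raise TypeError("pass either an LFRSpec or keyword overrides, not both")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    kmax = max(int(np.sqrt(n)), spec.min_degree + 1)
    kmin = spec.min_degree
    if spec.avg_degree is not None:
        best, best_err = kmin, np.inf
        for cand in range(1, kmax):
            support = np.arange(cand, kmax + 1).astype(float)
            w = support ** (-spec.tau1)
            mean = (support * w).sum() / w.sum()
            if abs(mean - spec.avg_degree) < best_err:
                best, best_err = cand, abs(mean - spec.avg_degree)
        kmin = best
    degrees = _powerlaw_choice(rng, kmin, kmax, spec.tau1, n)

    # community sizes: power law, truncated so the largest internal degree fits
    s_hi = max(kmax + 1, n // 4)
    s_lo = min(max(5, kmin + 1), s_hi)
    sizes: list[int] = []
    while sum(sizes) < n:
        sizes.append(int(_powerlaw_choice(rng, s_lo, s_hi, spec.tau2, 1)[0]))
    sizes[-1] -= sum(sizes) - n
    if sizes[-1] < s_lo:
        if len(sizes) > 1:
            sizes[-2] += sizes[-1]
            sizes.pop()
        # a single undersized community only occurs for tiny n; accept it

    internal = np.rint((1.0 - spec.mu) * degrees).astype(int)
    internal = np.minimum(internal, degrees)
    # assign nodes to communities, largest internal degree first, so that
    # every node's internal degree fits inside its community
    order = np.argsort(-internal)
    comms: list[list[int]] = [[] for _ in sizes]
    caps = list(sizes)
    for node in order:
        node = int(node)
        placed = False
        for ci in rng.permutation(len(comms)):
            if caps[ci] > 0 and internal[node] <= sizes[ci] - 1:
                comms[ci].append(node)
                caps[ci] -= 1
                placed = True
                break
        if not placed:  # shrink the internal degree to the largest community
            ci = int(np.argmax(caps))
            if caps[ci] <= 0:
                raise KeynodesError("community assignment failed; sizes infeasible")
            internal[node] = sizes[ci] - 1
            comms[ci].append(node)
            caps[ci] -= 1

    g = nx.Graph()
    g.add_nodes_from(range(n))

    def match_stubs(stubs: list[int], forbid_same_comm: dict[int, int] | None) -> None:
        """Randomly pair stubs, rejecting self-loops/multi-edges/intra pairs."""
        stubs = list(stubs)
        rng.shuffle(stubs)
        retries = 20 * len(stubs) + 10
        while len(stubs) > 1 and retries > 0:
            u = stubs.pop()
            v = stubs.pop()
            bad = u == v or g.has_edge(u, v)
            if forbid_same_comm is not None:
                bad = bad or forbid_same_comm[u] == forbid_same_comm[v]
            if bad:
                stubs.insert(0, u)
                stubs.insert(0, v)
                rng.shuffle(stubs)
                retries -= 1
            else:
                g.add_edge(u, v)

    comm_of: dict[int, int] = {}
    for ci, block in enumerate(comms):
        for x in block:
            comm_of[x] = ci
    for block in comms:
        stubs: list[int] = []
        for x in block:
            stubs.extend([x] * int(internal[x]))
        if len(stubs) % 2:
            # drop one stub so the internal count is even; at mu > 0 it is
            # re-spent as an external stub, at mu = 0 the degree just shrinks
            x = stubs.pop()
            internal[x] -= 1
            if spec.mu == 0:
                degrees[x] -= 1
        match_stubs(stubs, None)
    external_stubs: list[int] = []
    for x in range(n):
        external_stubs.extend([x] * int(degrees[x] - internal[x]))
    if len(external_stubs) % 2:
        external_stubs.pop()
    match_stubs(external_stubs, comm_of)

    net = ConductanceNetwork(g)
    membership = {str(x): (comm_of[x],) for x in range(n)}
    bridging = {
        str(x)
        for u, v in g.edges()
        if comm_of[u] != comm_of[v]
        for x in (u, v)
    }
    truth = PlantedTruth(membership=membership, overlapping=set(), bridging=bridging)
    return net, truth
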