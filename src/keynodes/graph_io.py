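"""Network input/output and bundled example networks.

Networks are held as :class:`ConductanceNetwork`: a labeled (di)graph in
which every edge carries a positive conductance (dimensionless; an edge is a
resistor of resistance ``1/conductance`` in the circuit mapping).  Supported
on-disk formats are plain edge lists (``u v [conductance]``, whitespace or
comma separated, ``#`` comments), GML and GraphML.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import ParseError, ValidationError

__all__ = [
    "ConductanceNetwork",
    "read_network",
    "write_network",
    "load_fixture",
    "FIXTURES",
]

FORMATS = ("edgelist", "gml", "graphml")

#: Bundled example networks, shipped as edge-list files.
FIXTURES = ("zachary", "schematic32", "twogroup13")

_FIXTURE_FILES = {
    "zachary": "zachary.edgelist",
    "schematic32": "schematic32_synthetic.edgelist",
    "twogroup13": "twogroup13.edgelist",
}


def natural_key(label: str):
    """Sort key putting numeric labels in numeric order ('2' before '10')."""
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", label)]


class ConductanceNetwork:
    """A labeled graph whose edges are conductances.

    Node labels are kept as strings internally (numeric labels keep their
    textual form).  Parallel edges are merged by *adding* their conductances,
    which is exact for resistors in parallel.  Self-loops and non-positive
    conductances are rejected.

    Parameters
    ----------
    graph
        A :class:`networkx.Graph` or :class:`networkx.DiGraph` whose edges
        carry a ``conductance`` attribute (missing values default to 1.0).
    """

    def __init__(self, graph: nx.Graph | nx.DiGraph):
        if graph.is_multigraph():
            raise ValidationError("multigraphs must be merged before wrapping")
        g = graph.__class__()
        for n in graph.nodes:
            g.add_node(str(n))
        for u, v, data in graph.edges(data=True):
            su, sv = str(u), str(v)
            c = float(data.get("conductance", data.get("weight", 1.0)))
            if su == sv:
                raise ValidationError(f"self-loop on node {su!r} is not allowed")
            if not c > 0:
                raise ValidationError(
                    f"edge ({su!r}, {sv!r}) has non-positive conductance {c}"
                )
            if g.has_edge(su, sv):
                g[su][sv]["conductance"] += c
            else:
                g.add_edge(su, sv, conductance=c)
        self.graph = g

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        directed: bool = False,
        nodes: Iterable | None = None,
    ) -> "ConductanceNetwork":
        """Build a network from ``(u, v)`` or ``(u, v, conductance)`` tuples."""
        g = nx.DiGraph() if directed else nx.Graph()
        if nodes is not None:
            g.add_nodes_from(str(n) for n in nodes)
        for e in edges:
            if len(e) == 2:
                u, v = e
                c = 1.0
            else:
                u, v, c = e
            u, v, c = str(u), str(v), float(c)
            if g.has_edge(u, v):
                g[u][v]["conductance"] += c
            else:
                g.add_edge(u, v, conductance=c)
        return cls(g)

    # -- basic views ----------------------------------------------------------

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def nodes(self) -> list[str]:
        """Node labels in natural sorted order."""
        return sorted(self.graph.nodes, key=natural_key)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as ``(u, v, conductance)``; undirected edges once each."""
        return [(u, v, d["conductance"]) for u, v, d in self.graph.edges(data=True)]

    @property
    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def conductance(self, u, v) -> float:
        return self.graph[str(u)][str(v)]["conductance"]

    def has_node(self, n) -> bool:
        return self.graph.has_node(str(n))

    def __contains__(self, n) -> bool:
        return self.has_node(n)

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return (
            f"<ConductanceNetwork {kind}, {self.number_of_nodes} nodes, "
            f"{self.number_of_edges} edges>"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConductanceNetwork):
            return NotImplemented
        if self.directed != other.directed:
            return False
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {(u, v): c for u, v, c in self.edges()}
        theirs = {(u, v): c for u, v, c in other.edges()}
        if not self.directed:
            mine = {tuple(sorted(k)): c for k, c in mine.items()}
            theirs = {tuple(sorted(k)): c for k, c in theirs.items()}
        if mine.keys() != theirs.keys():
            return False
        return all(abs(mine[k] - theirs[k]) <= 1e-12 * max(1.0, abs(mine[k])) for k in mine)


# -- readers / writers --------------------------------------------------------


def _parse_edgelist_lines(lines: Iterator[str]) -> Iterator[tuple[str, str, float]]:
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = [t for t in re.split(r"[,\s]+", line) if t]
        if len(tokens) not in (2, 3):
            raise ParseError(
                f"expected 'u v [conductance]', got {raw.strip()!r}", line=lineno
            )
        u, v = tokens[0], tokens[1]
        if len(tokens) == 3:
            try:
                c = float(tokens[2])
            except ValueError:
                raise ParseError(
                    f"conductance {tokens[2]!r} is not a number", line=lineno
                ) from None
        else:
            c = 1.0
        yield u, v, c


def read_network(
    path: str | Path, format: str = "edgelist", directed: bool = False
) -> ConductanceNetwork:
    """Read a network from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``edgelist``, ``gml``, ``graphml``.
    directed
        Edge-list files carry no directedness; this flag decides it.  For GML
        and GraphML the file's own directedness wins and the flag is ignored.

    Missing conductances default to 1.0; duplicate (parallel) edges are merged
    by adding conductances.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {FORMATS}")
    if format == "edgelist":
        with open(path) as fh:
            edges = list(_parse_edgelist_lines(fh))
        return ConductanceNetwork.from_edges(edges, directed=directed)
    if format == "gml":
        g = nx.read_gml(path, label="label")
    else:
        g = nx.read_graphml(path)
    return ConductanceNetwork(g)


def write_network(
    net: ConductanceNetwork, path: str | Path, format: str = "edgelist"
) -> None:
    """Write ``net`` so that :func:`read_network` reproduces it exactly."""
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {FORMATS}")
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("# u\tv\tconductance\n")
            for u, v, c in sorted(net.edges(), key=lambda e: (natural_key(e[0]), natural_key(e[1]))):
                fh.write(f"{u}\t{v}\t{c!r}\n")
    elif format == "gml":
        nx.write_gml(net.graph, path)
    else:
        nx.write_graphml(net.graph, path)


def load_fixture(name: str) -> ConductanceNetwork:
    """Load one of the bundled example networks.

    ``zachary``
        The classic 34-member karate-club friendship network (78 edges,
        1-based labels).
    ``schematic32``
        A synthetic 32-node network with three communities joined only
        through three connector nodes: node 12 straddles two communities
        (overlapping), nodes 16 and 24 are intra-community hubs holding a
        couple of edges into a foreign community (bridging).
    ``twogroup13``
        A 13-node network of two mirrored 6-node groups whose gateways (6, 8)
        are joined both directly and through the central connector node 7 —
        so node 7 lies on no shortest path yet carries substantial current.
    """
    if name not in _FIXTURE_FILES:
        raise ValueError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURES)}"
        )
    ref = resources.files("keynodes.data") / _FIXTURE_FILES[name]
    with resources.as_file(ref) as p:
        return read_network(p, format="edgelist", directed=False)
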