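"""Imbalance index D: separating bridging nodes from overlapping nodes.

Both node types carry high current, but they distribute it differently.  A
bridging node funnels the inter-community current through one (or very few)
bridging edges, so among its incident currents one value dominates.  An
overlapping node shares the same current across its dense connections into
each community, so its incident currents are comparatively balanced.  The
index captures this as *max minus median* of a node's incident currents; an
even count of values takes the midpoint of the two middle ones.  Degree-one
nodes (a single incident value) score zero.

Two accumulation schemes are offered:

``per_configuration`` (pipeline default)
    The max-minus-median is evaluated on the incident absolute currents of
    every individual source-target configuration and summed over the sweep.
    A bridging node shows a dominant edge in each configuration regardless
    of *which* edge dominates, so the signal survives pooling.

``accumulated``
    The max-minus-median is evaluated once on the table of accumulated
    absolute flows ``T``.  Cheaper, but a node whose dominant edge changes
    from configuration to configuration (typical of hubs that straddle
    communities) averages out and can be under- or over-scored.

Normalization is global: raw values are divided by the maximum raw value
over all nodes, so scores lie in [0, 1] and the method stays free of any
community partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centrality import FlowProfile
from .circuit import EdgeFlowTable
from .graph_io import ConductanceNetwork

__all__ = ["ImbalanceResult", "d_index", "d_index_per_configuration"]


@dataclass
class ImbalanceResult:
    """Raw and globally max-normalized imbalance per node."""

    raw: dict[str, float]
    normalized: dict[str, float]

    def __getitem__(self, node) -> float:
        return self.normalized[str(node)]


def _normalize(raw: dict[str, float]) -> ImbalanceResult:
    mx = max(raw.values(), default=0.0)
    if mx > 0:
        normalized = {n: v / mx for n, v in raw.items()}
    else:
        normalized = {n: 0.0 for n in raw}
    return ImbalanceResult(raw=dict(raw), normalized=normalized)


def d_index(net: ConductanceNetwork, T: EdgeFlowTable) -> ImbalanceResult:
    """Imbalance from an accumulated flow table (``accumulated`` scheme).

    ``T`` must be an ``accumulated_absolute`` table covering every edge of
    the network (for directed networks, with opposite arcs already merged).
    """
    if T.mode != "accumulated_absolute":
        raise ValueError("d_index needs an accumulated_absolute flow table")
    undirected = net.graph.to_undirected(as_view=True) if net.directed else net.graph
    raw: dict[str, float] = {}
    for n in net.nodes:
        vals = []
        for nb in undirected.neighbors(n):
            try:
                vals.append(T.flow(n, nb))
            except KeyError:
                raise ValueError(
                    f"flow table is missing edge ({n!r}, {nb!r})"
                ) from None
        if len(vals) < 2:
            raw[n] = 0.0
        else:
            raw[n] = float(max(vals) - np.median(vals))
    return _normalize(raw)


def d_index_per_configuration(profile: FlowProfile) -> ImbalanceResult:
    """Imbalance accumulated configuration by configuration (default scheme).

    Takes the per-node max-minus-median sums produced by the flow sweep
    (:func:`keynodes.centrality.flow_profile`) and normalizes them by the
    global maximum.
    """
    return _normalize(profile.imbalance_raw)
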