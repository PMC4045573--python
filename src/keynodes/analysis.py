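"""Key-node selection and classification: the end-to-end analysis driver.

Key nodes are the top fraction ``q`` (default 10%) of nodes by current-flow
centrality — the point where the empirical CDF of C reaches ``1 - q``.  The
quantile is computed by rank, so the threshold is a value an actual node
attains; nodes tied with the threshold are all included.  Key nodes are
then split by the normalized imbalance index: ``D >= d_threshold`` (default
0.5) marks a bridging node, lower values an overlapping node.  No exact
separating threshold exists in general, so ``d_threshold`` is a declared,
configurable heuristic; a 2-means split of D among the key nodes is
available as an alternative rule.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .centrality import NodeScoreTable, flow_profile, shortest_path_betweenness
from .errors import KeynodesError
from .graph_io import ConductanceNetwork, natural_key
from .imbalance import ImbalanceResult, d_index, d_index_per_configuration

__all__ = [
    "AnalysisConfig",
    "KeyNodeReport",
    "select_key_nodes",
    "classify_key_nodes",
    "analyze",
]

_TIE_RTOL = 1e-9


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline, with repository defaults."""

    q: float = 0.10
    d_threshold: float = 0.5
    classifier: str = "threshold"  # "threshold" | "two_means"
    imbalance: str = "per_configuration"  # "per_configuration" | "accumulated"
    ground_conductance: float = 1.0
    solver_tol: float = 1e-10
    solver_max_iter: int = 100_000
    damping: float = 0.5
    include_betweenness: bool = True


@dataclass
class KeyNodeReport:
    """Serializable result of one analysis run."""

    schema_version: int
    directed: bool
    n_nodes: int
    n_edges: int
    quantile_q: float
    threshold_C: float
    d_threshold: float
    classifier: str
    imbalance_scheme: str
    key_nodes: list[str]
    overlapping: list[str]
    bridging: list[str]
    centrality: dict[str, float]
    imbalance: dict[str, float]
    betweenness: dict[str, float] | None
    pair_count: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False)


def select_key_nodes(
    scores: NodeScoreTable, q: float = 0.10
) -> tuple[float, set[str]]:
    """Top fraction ``q`` of nodes by score, with threshold ties included.

    Returns ``(threshold, key_nodes)`` where the threshold is the score of
    the ``floor(q * N)``-th ranked node (at least one), i.e. the value at
    which the empirical CDF of the scores reaches ``1 - q``.  If every node
    scores identically no node is distinguishable: an empty set is returned
    with a warning.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if scores.scheme not in ("C_undirected", "C_directed"):
        raise ValueError("key nodes are selected on a current-flow centrality table")
    ranked = scores.ranked()
    values = [v for _, v in ranked]
    if math.isclose(min(values), max(values), rel_tol=_TIE_RTOL, abs_tol=0.0):
        warnings.warn(
            "all centrality scores are equal; no key node is distinguishable",
            stacklevel=2,
        )
        return float(values[0]), set()
    k = max(1, int(math.floor(q * len(ranked) + 1e-12)))
    threshold = ranked[k - 1][1]
    key = {
        n
        for n, v in ranked
        if v > threshold or math.isclose(v, threshold, rel_tol=_TIE_RTOL)
    }
    return float(threshold), key


def _two_means_split(values: dict[str, float]) -> float:
    """1-D 2-means threshold (midpoint of the two final cluster means)."""
    x = np.sort(np.fromiter(values.values(), dtype=float))
    lo, hi = x[0], x[-1]
    if lo == hi:
        return hi + 1.0  # single cluster: nothing above the threshold
    cut = 0.5 * (lo + hi)
    for _ in range(100):
        left = x[x < cut]
        right = x[x >= cut]
        if len(left) == 0 or len(right) == 0:
            break
        new = 0.5 * (left.mean() + right.mean())
        if abs(new - cut) < 1e-12:
            break
        cut = new
    return float(cut)


def classify_key_nodes(
    key_nodes: set[str],
    D: ImbalanceResult,
    d_threshold: float = 0.5,
    classifier: str = "threshold",
) -> tuple[set[str], set[str]]:
    """Split key nodes into (overlapping, bridging) by normalized imbalance.

    ``threshold``: bridging iff ``D >= d_threshold``.  ``two_means``: the
    threshold is instead a 2-means split of the key nodes' D values.
    """
    missing = [n for n in key_nodes if n not in D.normalized]
    if missing:
        raise KeynodesError(f"key nodes missing from the imbalance result: {missing}")
    if classifier == "two_means":
        if key_nodes:
            cut = _two_means_split({n: D.normalized[n] for n in key_nodes})
        else:
            cut = d_threshold
    elif classifier == "threshold":
        cut = d_threshold
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    bridging = {n for n in key_nodes if D.normalized[n] >= cut}
    overlapping = set(key_nodes) - bridging
    return overlapping, bridging


def analyze(net: ConductanceNetwork, config: AnalysisConfig | None = None) -> KeyNodeReport:
    """Full pipeline: sweep -> C -> T -> D -> quantile threshold -> classify."""
    cfg = config or AnalysisConfig()
    notes: list[str] = []
    try:
        profile = flow_profile(
            net,
            ground_conductance=cfg.ground_conductance,
            tol=cfg.solver_tol,
            max_iter=cfg.solver_max_iter,
            damping=cfg.damping,
        )
    except KeynodesError as exc:
        raise KeynodesError(f"[sweep] {exc}") from exc
    C = profile.centrality
    if cfg.imbalance == "per_configuration":
        D = d_index_per_configuration(profile)
    elif cfg.imbalance == "accumulated":
        D = d_index(net, profile.accumulated)
    else:
        raise ValueError(f"unknown imbalance scheme {cfg.imbalance!r}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        threshold, key = select_key_nodes(C, q=cfg.q)
    notes.extend(str(w.message) for w in caught)
    try:
        overlapping, bridging = classify_key_nodes(
            key, D, d_threshold=cfg.d_threshold, classifier=cfg.classifier
        )
    except KeynodesError as exc:
        raise KeynodesError(f"[classify] {exc}") from exc

    bt = shortest_path_betweenness(net) if cfg.include_betweenness and not net.directed else None
    order = sorted(C.scores, key=natural_key)

    def by_order(d: dict[str, float]) -> dict[str, float]:
        return {n: d[n] for n in order}

    return KeyNodeReport(
        schema_version=1,
        directed=net.directed,
        n_nodes=net.number_of_nodes,
        n_edges=net.number_of_edges,
        quantile_q=cfg.q,
        threshold_C=threshold,
        d_threshold=cfg.d_threshold,
        classifier=cfg.classifier,
        imbalance_scheme=cfg.imbalance,
        key_nodes=sorted(key, key=natural_key),
        overlapping=sorted(overlapping, key=natural_key),
        bridging=sorted(bridging, key=natural_key),
        centrality=by_order(C.scores),
        imbalance=by_order(D.normalized),
        betweenness=by_order(bt.scores) if bt is not None else None,
        pair_count=profile.pair_count,
        warnings=notes,
    )
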