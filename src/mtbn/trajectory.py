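"""Most-likely comorbidity trajectories by longest path over a weighted DAG.

Condition-level edges of a learned network are weighted with empirical
co-activation log-probabilities, ln P(child active | parent active) with
add-one smoothing, so that a path's summed weight is the log of a product of
conditional probabilities and the longest (maximum-weight) path is the most
likely comorbidity sequence. A dummy source node wired to every first-year
condition (weighted by log first-year prevalence) reduces "from any
comorbidity" queries to a single-source longest path; a dummy sink plays the
symmetric role for "emerging from" queries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data_model import LongitudinalCohort
from .structure import DagStructure, NodeId, StructureError

__all__ = [
    "SOURCE",
    "SINK",
    "WeightedDag",
    "TrajectoryPath",
    "edge_weights",
    "attach_dummy_source",
    "attach_dummy_sink",
    "longest_path",
    "all_paths",
    "path_support",
]

SOURCE = NodeId("SOURCE", None, "dummy")
SINK = NodeId("SINK", None, "dummy")


@dataclass
class WeightedDag:
    """Condition-level DAG with log-probability edge weights (dummy edges may be 0)."""

    nodes: set[NodeId]
    weights: dict[tuple[NodeId, NodeId], float]

    def successors(self, node: NodeId) -> list[NodeId]:
        return sorted(v for (u, v) in self.weights if u == node)

    def topological_order(self) -> list[NodeId]:
        indeg = {n: 0 for n in self.nodes}
        for _, v in self.weights:
            indeg[v] += 1
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[NodeId] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for c in self.successors(n):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
            ready.sort()
        if len(order) != len(self.nodes):
            raise StructureError("weighted graph contains a cycle")
        return order


@dataclass(frozen=True)
class TrajectoryPath:
    """An ordered (condition, year) node sequence with its cumulative log-weight."""

    nodes: tuple[NodeId, ...]
    log_weight: float

    @property
    def probability(self) -> float:
        return math.exp(self.log_weight)


def edge_weights(
    dag: DagStructure,
    cohort: LongitudinalCohort,
    scheme: str = "empirical_coactivation",
) -> WeightedDag:
    """Weight every condition-condition edge with ln P(child=1 | parent=1).

    The estimate uses add-one smoothing, (N(parent=1, child=1) + 1) /
    (N(parent=1) + 2), so a parent condition never active in the cohort still
    yields a finite (smoothed) weight. Demographic nodes and their edges are
    excluded; all weights are <= 0.
    """
    if scheme != "empirical_coactivation":
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    nodes = set(dag.condition_nodes)
    weights: dict[tuple[NodeId, NodeId], float] = {}
    for u, v in dag.edges:
        if u.kind != "condition" or v.kind != "condition":
            continue
        xu = cohort.condition_values(u.slice, u.name)
        xv = cohort.condition_values(v.slice, v.name)
        n_u = int(xu.sum())
        n_uv = int((xu & xv).sum())
        weights[(u, v)] = math.log((n_uv + 1) / (n_u + 2))
    return WeightedDag(nodes=nodes, weights=weights)


def attach_dummy_source(wdag: WeightedDag, cohort: LongitudinalCohort) -> WeightedDag:
    """Add a dummy source wired to every first-year condition node.

    Source edges carry ln of the add-one-smoothed first-year prevalence, so a
    source-to-sink path weight stays a log-probability.
    """
    if SOURCE in wdag.nodes:
        raise StructureError("graph already has a dummy source")
    nodes = set(wdag.nodes) | {SOURCE}
    weights = dict(wdag.weights)
    n = cohort.n_patients
    for node in sorted(wdag.nodes):
        if node.kind == "condition" and node.slice == 0:
            k = int(cohort.condition_values(0, node.name).sum())
            weights[(SOURCE, node)] = math.log((k + 1) / (n + 2))
    return WeightedDag(nodes=nodes, weights=weights)


def attach_dummy_sink(wdag: WeightedDag, cohort: LongitudinalCohort) -> WeightedDag:
    """Add a dummy sink fed by every last-year condition node (weight 0).

    Sink edges are weightless so that the path probability remains that of
    reaching the last real node.
    """
    if SINK in wdag.nodes:
        raise StructureError("graph already has a dummy sink")
    last = max(n.slice for n in wdag.nodes if n.kind == "condition")
    nodes = set(wdag.nodes) | {SINK}
    weights = dict(wdag.weights)
    for node in sorted(wdag.nodes):
        if node.kind == "condition" and node.slice == last:
            weights[(node, SINK)] = 0.0
    return WeightedDag(nodes=nodes, weights=weights)


def longest_path(
    wdag: WeightedDag, source: NodeId, sink: NodeId
) -> TrajectoryPath | None:
    """Maximum-weight source-to-sink path by DP over a topological order.

    Ties are broken by shorter path, then by the lexicographic sequence of
    node names. Returns ``None`` when no path exists.
    """
    if source not in wdag.nodes or sink not in wdag.nodes:
        raise ValueError("source and sink must be nodes of the graph")
    order = wdag.topological_order()  # also rejects cyclic input
    # best[v] = (weight, length, name-sequence, node-path)
    best: dict[NodeId, tuple[float, int, tuple[str, ...], tuple[NodeId, ...]]] = {
        source: (0.0, 0, (str(source),), (source,))
    }
    for u in order:
        if u not in best:
            continue
        w_u, len_u, names_u, path_u = best[u]
        for v in wdag.successors(u):
            w = w_u + wdag.weights[(u, v)]
            cand = (w, len_u + 1, names_u + (str(v),), path_u + (v,))
            cur = best.get(v)
            if cur is None or (-cand[0], cand[1], cand[2]) < (-cur[0], cur[1], cur[2]):
                best[v] = cand
    if sink not in best:
        return None
    w, _, _, path = best[sink]
    return TrajectoryPath(nodes=path, log_weight=w)


def all_paths(wdag: WeightedDag, source: NodeId, sink: NodeId) -> list[TrajectoryPath]:
    """Exhaustive path enumeration (test oracle for small graphs)."""
    out: list[TrajectoryPath] = []

    def walk(node: NodeId, acc: tuple[NodeId, ...], weight: float) -> None:
        if node == sink:
            out.append(TrajectoryPath(acc, weight))
            return
        for v in wdag.successors(node):
            walk(v, acc + (v,), weight + wdag.weights[(node, v)])

    walk(source, (source,), 0.0)
    return out


def path_support(cohort: LongitudinalCohort, path: TrajectoryPath) -> float:
    """Fraction of sink-positive patients whose panels realise the whole path.

    The sink is the path's last (condition, year) node; dummy nodes are
    ignored. Raises ``ValueError`` when no patient is positive at the sink.
    """
    real = [n for n in path.nodes if n.kind == "condition"]
    if not real:
        raise ValueError("path contains no condition nodes")
    sink = real[-1]
    sink_pos = cohort.condition_values(sink.slice, sink.name).astype(bool)
    denom = int(sink_pos.sum())
    if denom == 0:
        raise ValueError(f"no patient is positive at {sink}; support undefined")
    match = np.ones(cohort.n_patients, dtype=bool)
    for node in real:
        match &= cohort.condition_values(node.slice, node.name).astype(bool)
    return float(match[sink_pos].mean() if denom else math.nan)
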