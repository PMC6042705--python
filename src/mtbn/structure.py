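"""Structure learning for multi-level temporal Bayesian networks.

Three learning modes over (condition, year) nodes:

* **unsupervised** — a Chow–Liu style maximum-weight spanning tree on pairwise
  mutual information is built per time slice to obtain a within-slice node
  ordering; the per-slice orderings are concatenated by slice into one
  topological ordering; a K2 greedy search with the Cooper–Herskovits family
  score then picks parents under that ordering.
* **semi_supervised** — an expert-supplied node ordering feeds the same K2
  search.
* **supervised** — an expert-supplied DAG is validated and used as-is.

A higher demographic level (race, gender, ...) is attached afterwards by
connecting every demographic variable to every condition node; demographic
nodes never receive parents and are never connected to each other.

The spanning tree supplies the ordering only; its edges are not forced into
the final DAG. Cross-slice condition edges are restricted to a configurable
window of consecutive slices (default: t -> t+1 only), which includes
same-condition persistence edges.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .data_model import LongitudinalCohort

__all__ = [
    "NodeId",
    "condition_node",
    "demographic_node",
    "DagStructure",
    "StructureError",
    "pairwise_mutual_information",
    "mwst_slice",
    "integrate_orderings",
    "k2_family_score",
    "bic_family_score",
    "k2_search",
    "learn_structure",
    "add_demographic_level",
    "structure_similarity",
    "write_edge_list",
    "read_edge_list",
    "to_dot",
]


class StructureError(ValueError):
    """Raised for DAG-invariant violations or malformed learning inputs."""


@dataclass(frozen=True)
class NodeId:
    """A network node: a (condition, year) pair or a demographic variable.

    ``slice`` is the 0-based year index for condition nodes and ``None`` for
    demographic (and dummy) nodes. The rendered name uses 1-based years,
    e.g. ``SuAb_y3``.
    """

    name: str
    slice: int | None = None
    kind: str = "condition"

    def __str__(self) -> str:
        if self.kind == "condition":
            return f"{self.name}_y{self.slice + 1}"
        return self.name

    def __lt__(self, other: "NodeId") -> bool:  # deterministic orderings
        return (self.kind, self.slice if self.slice is not None else -1, self.name) < (
            other.kind,
            other.slice if other.slice is not None else -1,
            other.name,
        )


def condition_node(name: str, year_index: int) -> NodeId:
    return NodeId(name=name, slice=int(year_index), kind="condition")


def demographic_node(name: str) -> NodeId:
    return NodeId(name=name, slice=None, kind="demographic")


class DagStructure:
    """A layered DAG over condition and demographic nodes.

    Invariants (enforced by :meth:`validate`): acyclicity; no edge between two
    demographic nodes; demographic nodes have no parents; no edge from a later
    to an earlier slice; cross-slice condition edges span at most ``window``
    slices.
    """

    def __init__(
        self,
        nodes: Iterable[NodeId] = (),
        edges: Iterable[tuple[NodeId, NodeId]] = (),
    ) -> None:
        self.nodes: set[NodeId] = set(nodes)
        self.edges: set[tuple[NodeId, NodeId]] = set()
        for u, v in edges:
            self.add_edge(u, v)

    def add_edge(self, parent: NodeId, child: NodeId) -> None:
        self.nodes.add(parent)
        self.nodes.add(child)
        self.edges.add((parent, child))

    def parents(self, node: NodeId) -> tuple[NodeId, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def children(self, node: NodeId) -> tuple[NodeId, ...]:
        return tuple(sorted(v for u, v in self.edges if u == node))

    @property
    def condition_nodes(self) -> tuple[NodeId, ...]:
        return tuple(sorted(n for n in self.nodes if n.kind == "condition"))

    @property
    def demographic_nodes(self) -> tuple[NodeId, ...]:
        return tuple(sorted(n for n in self.nodes if n.kind == "demographic"))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[NodeId]:
        """Deterministic topological order (Kahn, ties by node sort order)."""
        indeg = {n: 0 for n in self.nodes}
        for _, v in self.edges:
            indeg[v] += 1
        ready = sorted(n for n, d in indeg.items() if d == 0)
        order: list[NodeId] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            changed = False
            for c in self.children(n):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
                    changed = True
            if changed:
                ready.sort()
        if len(order) != len(self.nodes):
            raise StructureError("graph contains a cycle")
        return order

    def validate(self, window: int = 1) -> None:
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise StructureError("graph contains a cycle")
        for u, v in self.edges:
            if u.kind == "demographic" and v.kind == "demographic":
                raise StructureError(f"edge between demographic nodes {u} -> {v}")
            if v.kind == "demographic":
                raise StructureError(f"demographic node {v} has a parent")
            if u.kind == "condition" and v.kind == "condition":
                if u.slice > v.slice:
                    raise StructureError(f"backwards-in-time edge {u} -> {v}")
                if v.slice - u.slice > window:
                    raise StructureError(
                        f"cross-slice edge {u} -> {v} exceeds window {window}"
                    )

    def copy(self) -> "DagStructure":
        return DagStructure(self.nodes, self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DagStructure):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"DagStructure({len(self.nodes)} nodes, {len(self.edges)} edges)"


# -- mutual information and per-slice spanning tree ------------------------

def pairwise_mutual_information(
    cohort: LongitudinalCohort, year_index: int
) -> np.ndarray:
    """Plug-in mutual information (nats) between every condition pair in one slice.

    MI(X;Y) = sum_{x,y} p(x,y) ln p(x,y) / (p(x) p(y)) with empirical
    probabilities and the 0 ln 0 := 0 convention. Diagonal is zero by
    convention; the matrix is symmetric and non-negative.
    """
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    if not 0 <= year_index < cohort.n_years:
        raise ValueError(f"year index {year_index} out of range")
    X = cohort.panel[:, year_index, :].astype(np.int64)
    n, C = X.shape
    mi = np.zeros((C, C))
    p1 = X.mean(axis=0)
    for i in range(C):
        for j in range(i + 1, C):
            n11 = float(np.sum((X[:, i] == 1) & (X[:, j] == 1)))
            joint = np.array(
                [
                    [n - X[:, i].sum() - X[:, j].sum() + n11, X[:, j].sum() - n11],
                    [X[:, i].sum() - n11, n11],
                ]
            ) / n
            value = 0.0
            for a in (0, 1):
                for b in (0, 1):
                    pa = p1[i] if a else 1 - p1[i]
                    pb = p1[j] if b else 1 - p1[j]
                    if joint[a, b] > 0:
                        value += joint[a, b] * math.log(joint[a, b] / (pa * pb))
            mi[i, j] = mi[j, i] = max(value, 0.0)
    return mi


def mwst_slice(
    mi: np.ndarray, condition_names: Sequence[str]
) -> tuple[list[tuple[str, str]], list[str]]:
    """Maximum-weight spanning tree of one slice's MI graph, plus an ordering.

    Kruskal over the complete graph, edges sorted by descending MI with ties
    broken by the lexicographic (name, name) pair. The ordering is a
    breadth-first traversal from the root (the node with maximal MI row-sum,
    ties lexicographic); children are visited by descending edge MI then name.
    """
    names = list(condition_names)
    C = len(names)
    if C == 0:
        raise ValueError("need at least one condition")
    if C == 1:
        return [], [names[0]]
    candidates = sorted(
        ((i, j) for i in range(C) for j in range(i + 1, C)),
        key=lambda ij: (-mi[ij], tuple(sorted((names[ij[0]], names[ij[1]])))),
    )
    parent = list(range(C))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int]] = []
    for i, j in candidates:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j))
            if len(tree) == C - 1:
                break

    row_sum = mi.sum(axis=1)
    root = min(range(C), key=lambda i: (-row_sum[i], names[i]))
    adjacency: dict[int, list[int]] = {i: [] for i in range(C)}
    for i, j in tree:
        adjacency[i].append(j)
        adjacency[j].append(i)
    ordering: list[str] = []
    visited = {root}
    queue = [root]
    while queue:
        u = queue.pop(0)
        ordering.append(names[u])
        nbrs = sorted(
            (v for v in adjacency[u] if v not in visited),
            key=lambda v: (-mi[u, v], names[v]),
        )
        visited.update(nbrs)
        queue.extend(nbrs)
    edges = [tuple(sorted((names[i], names[j]))) for i, j in tree]
    return edges, ordering


def integrate_orderings(per_slice_orderings: Sequence[Sequence[str]]) -> list[NodeId]:
    """Concatenate within-slice orderings by ascending slice into one total order."""
    if not per_slice_orderings:
        raise ValueError("need at least one slice ordering")
    base = sorted(per_slice_orderings[0])
    for t, ordering in enumerate(per_slice_orderings):
        if sorted(ordering) != base:
            raise StructureError(
                f"slice {t} ordering is over a different condition set"
            )
    return [
        condition_node(name, t)
        for t, ordering in enumerate(per_slice_orderings)
        for name in ordering
    ]


# -- family scores ---------------------------------------------------------

def k2_family_score(
    child_values: np.ndarray,
    parent_config_ids: np.ndarray,
    r_child: int,
    n_parent_configs: int | None = None,
) -> float:
    """Cooper–Herskovits log marginal likelihood of one node's family.

    log prod_j (r-1)! / (N_j + r - 1)! * prod_k N_jk!, evaluated with
    log-gamma. ``parent_config_ids`` enumerates joint parent states per
    observation (all zeros for a parentless node).
    """
    child_values = np.asarray(child_values, dtype=np.int64)
    if child_values.size == 0:
        raise ValueError("empty child vector")
    parent_config_ids = np.asarray(parent_config_ids, dtype=np.int64)
    q = int(n_parent_configs or parent_config_ids.max() + 1)
    counts = np.bincount(
        parent_config_ids * r_child + child_values, minlength=q * r_child
    ).reshape(q, r_child)
    n_j = counts.sum(axis=1)
    score = (
        q * gammaln(r_child)
        - gammaln(n_j + r_child).sum()
        + gammaln(counts + 1).sum()
    )
    return float(score)


def bic_family_score(
    child_values: np.ndarray,
    parent_config_ids: np.ndarray,
    r_child: int,
    n_parent_configs: int | None = None,
) -> float:
    """Maximum log-likelihood with a BIC penalty (alternative family score)."""
    child_values = np.asarray(child_values, dtype=np.int64)
    if child_values.size == 0:
        raise ValueError("empty child vector")
    parent_config_ids = np.asarray(parent_config_ids, dtype=np.int64)
    q = int(n_parent_configs or parent_config_ids.max() + 1)
    counts = np.bincount(
        parent_config_ids * r_child + child_values, minlength=q * r_child
    ).reshape(q, r_child)
    n_j = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / n_j), 0.0).sum()
    n = child_values.size
    return float(ll - 0.5 * math.log(n) * q * (r_child - 1))


_SCORERS = {"k2": k2_family_score, "bic": bic_family_score}


# -- K2 greedy search -------------------------------------------------------

def _node_values(cohort: LongitudinalCohort, node: NodeId) -> np.ndarray:
    if node.kind != "condition":
        raise StructureError(f"K2 search operates on condition nodes, got {node}")
    return cohort.condition_values(node.slice, node.name)


def _config_ids(columns: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Joint parent-state ids (binary parents) and the number of configs."""
    if not columns:
        return np.zeros(1, dtype=np.int64), 1
    ids = np.zeros_like(columns[0])
    for col in columns:
        ids = ids * 2 + col
    return ids, 2 ** len(columns)


def k2_search(
    ordering: Sequence[NodeId],
    cohort: LongitudinalCohort,
    max_parents: int = 3,
    window: int = 1,
    score: Literal["k2", "bic"] = "k2",
) -> DagStructure:
    """K2 greedy parent selection under a fixed node ordering.

    For each node in order, repeatedly adds the single admissible predecessor
    that most increases the family score, stopping when no addition improves
    the score or ``max_parents`` is reached. Admissible predecessors are
    earlier nodes of the same slice or of a slice within ``window`` before the
    node's slice. Ties in score gain are broken by node sort order, for
    determinism.
    """
    scorer = _SCORERS[score]
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    dag = DagStructure(nodes=ordering)
    ordering = list(ordering)
    values = {node: _node_values(cohort, node) for node in ordering}
    n = cohort.n_patients
    if n == 0:
        raise ValueError("empty cohort")

    for i, node in enumerate(ordering):
        candidates = [
            p
            for p in ordering[:i]
            if p.slice == node.slice or 0 <= node.slice - p.slice <= window
        ]
        parents: list[NodeId] = []
        cols: list[np.ndarray] = []
        ids, q = _config_ids(cols)
        best = scorer(values[node], ids, 2, q)
        while len(parents) < max_parents and candidates:
            gains = []
            for cand in sorted(candidates):
                ids, q = _config_ids(cols + [values[cand]])
                gains.append((scorer(values[node], ids, 2, q), cand))
            top_score, top = max(gains, key=lambda g: (g[0],))
            if top_score > best:
                best = top_score
                parents.append(top)
                cols.append(values[top])
                candidates.remove(top)
            else:
                break
        for p in parents:
            dag.add_edge(p, node)
    return dag


# -- learning modes ----------------------------------------------------------

def learn_structure(
    cohort: LongitudinalCohort,
    mode: Literal["unsupervised", "semi_supervised", "supervised"] = "unsupervised",
    expert_ordering: Sequence[NodeId] | None = None,
    expert_dag: DagStructure | None = None,
    max_parents: int = 3,
    window: int = 1,
    score: Literal["k2", "bic"] = "k2",
) -> DagStructure:
    """Learn the condition-level DAG in one of the three modes.

    The demographic layer is attached separately with
    :func:`add_demographic_level`. Unsupervised learning is deterministic
    given the cohort and settings (no randomness is involved).
    """
    if mode == "supervised":
        if expert_dag is None:
            raise ValueError("supervised mode requires an expert DAG")
        expert_dag.validate(window=window)
        return expert_dag.copy()
    if mode == "semi_supervised":
        if expert_ordering is None:
            raise ValueError("semi-supervised mode requires an expert node ordering")
        _check_ordering(expert_ordering, cohort)
        return k2_search(expert_ordering, cohort, max_parents, window, score)
    if mode == "unsupervised":
        per_slice = []
        for t in range(cohort.n_years):
            mi = pairwise_mutual_information(cohort, t)
            _, ordering = mwst_slice(mi, cohort.condition_names)
            per_slice.append(ordering)
        node_order = integrate_orderings(per_slice)
        return k2_search(node_order, cohort, max_parents, window, score)
    raise ValueError(f"unknown mode {mode!r}")


def _check_ordering(ordering: Sequence[NodeId], cohort: LongitudinalCohort) -> None:
    expected = {
        condition_node(c, t)
        for c in cohort.condition_names
        for t in range(cohort.n_years)
    }
    if set(ordering) != expected or len(ordering) != len(expected):
        raise StructureError("ordering must cover every condition node exactly once")
    last_slice = -1
    for node in ordering:
        if node.slice < last_slice:
            raise StructureError("ordering violates slice monotonicity")
        last_slice = node.slice


def add_demographic_level(
    dag: DagStructure, demographic_schema: Mapping[str, Sequence[str]]
) -> DagStructure:
    """Attach the demographic layer: every demographic -> every condition node.

    Demographic nodes receive no parents and are never connected to each
    other; this step bypasses any parent cap.
    """
    if dag.demographic_nodes:
        raise StructureError("DAG already carries a demographic level")
    condition_names = {n.name for n in dag.condition_nodes}
    collisions = condition_names & set(demographic_schema)
    if collisions:
        raise StructureError(
            f"demographic variables collide with condition names: {sorted(collisions)}"
        )
    out = dag.copy()
    for var in demographic_schema:
        d = demographic_node(var)
        out.nodes.add(d)
        for cnode in dag.condition_nodes:
            out.add_edge(d, cnode)
    return out


# -- structure similarity -----------------------------------------------------

def structure_similarity(a: DagStructure, b: DagStructure) -> tuple[float, float]:
    """Cosine and Pearson similarity of two DAGs' condition-level adjacency.

    Both DAGs are flattened to binary adjacency vectors over their common
    condition-node set (demographic layers, identical by construction across
    learning modes, are excluded). Returned as percentages.
    """
    nodes_a, nodes_b = set(a.condition_nodes), set(b.condition_nodes)
    if nodes_a != nodes_b:
        raise StructureError("structures are over different condition-node sets")
    nodes = sorted(nodes_a)
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    va = np.array([(u, v) in a.edges for u, v in pairs], dtype=float)
    vb = np.array([(u, v) in b.edges for u, v in pairs], dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    cosine = float(va @ vb / (na * nb)) if na > 0 and nb > 0 else 0.0
    if va.std() == 0 or vb.std() == 0:
        pearson = math.nan
    else:
        pearson = float(np.corrcoef(va, vb)[0, 1])
    return 100.0 * cosine, 100.0 * pearson


# -- graph file IO ------------------------------------------------------------

def _parse_node(
    token: str,
    condition_names: Sequence[str],
    demographic_vars: Sequence[str],
) -> NodeId:
    if token in demographic_vars:
        return demographic_node(token)
    m = itertools.chain(
        (c for c in condition_names if token.startswith(f"{c}_y")), ()
    )
    for cond in m:
        year = token[len(cond) + 2 :]
        if year.isdigit():
            return condition_node(cond, int(year) - 1)
    raise StructureError(f"cannot parse node name {token!r}")


def write_edge_list(dag: DagStructure, dest) -> None:
    """Edge-list CSV (``parent,child``), rows sorted for reproducible diffs."""
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w", newline="")
        close = True
    try:
        writer = csv.writer(dest)
        writer.writerow(["parent", "child"])
        for u, v in sorted(dag.edges, key=lambda e: (str(e[0]), str(e[1]))):
            writer.writerow([str(u), str(v)])
    finally:
        if close:
            dest.close()


def read_edge_list(
    source,
    condition_names: Sequence[str],
    demographic_vars: Sequence[str] = (),
    nodes: Iterable[NodeId] = (),
) -> DagStructure:
    """Read an edge-list CSV written by :func:`write_edge_list`.

    ``nodes`` may add isolated nodes not mentioned by any edge.
    """
    close = False
    if isinstance(source, (str, bytes)):
        source = open(source, newline="")
        close = True
    try:
        reader = csv.reader(source)
        header = next(reader)
        if [h.strip() for h in header] != ["parent", "child"]:
            raise StructureError("edge-list file must have a parent,child header")
        dag = DagStructure(nodes=nodes)
        for row in reader:
            if not row:
                continue
            u = _parse_node(row[0].strip(), condition_names, demographic_vars)
            v = _parse_node(row[1].strip(), condition_names, demographic_vars)
            dag.add_edge(u, v)
        return dag
    finally:
        if close:
            source.close()


def to_dot(dag: DagStructure) -> str:
    """Graphviz DOT rendering; demographic nodes are boxed, slices ranked."""
    lines = ["digraph mtbn {", "  rankdir=LR;"]
    for node in sorted(dag.nodes, key=str):
        shape = "box" if node.kind == "demographic" else "ellipse"
        lines.append(f'  "{node}" [shape={shape}];')
    for u, v in sorted(dag.edges, key=lambda e: (str(e[0]), str(e[1]))):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
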