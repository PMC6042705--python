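"""Parameter estimation and exact inference for temporal Bayesian networks.

The joint distribution factorises over the DAG as the product of one
conditional probability table (CPT) per node given its parents. CPTs are
estimated from complete-case cohorts by (optionally Dirichlet-smoothed)
maximum likelihood:

    P(x | pa) = (N(x, pa) + alpha) / (N(pa) + alpha * r)

with ``alpha = 0`` giving the pure MLE; parent configurations never observed
at ``alpha = 0`` fall back to a uniform row (with a logged warning).

Queries are answered exactly by variable elimination: the network is first
pruned to the ancestors of the evidence and target nodes, factors are reduced
by the evidence, and the remaining variables are summed out along a min-fill
elimination order. A brute-force enumeration routine with the same contract
serves as an independent oracle for small networks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import LongitudinalCohort, all_state_codes, decode_state, default_digit_map
from .structure import DagStructure, NodeId, condition_node, demographic_node

__all__ = [
    "Cpt",
    "TemporalBayesNet",
    "ZeroEvidenceError",
    "fit_cpts",
    "joint_probability",
    "predictive_marginals",
    "posterior_joint",
    "brute_force_marginals",
    "transition_table",
    "profile_evidence",
    "save_network",
    "load_network",
]

logger = logging.getLogger(__name__)


class ZeroEvidenceError(ValueError):
    """Raised when the supplied evidence has probability zero under the model."""


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table for one node.

    ``table`` has one row per joint parent configuration (row-major in the
    order of ``parents`` with ``parent_cards`` levels each) and one column per
    node state; every row sums to one.
    """

    node: NodeId
    parents: tuple[NodeId, ...]
    parent_cards: tuple[int, ...]
    card: int
    table: np.ndarray
    alpha: float = 0.0

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_cards)) if self.parents else 1
        if table.shape != (q, self.card):
            raise ValueError(
                f"CPT for {self.node} has shape {table.shape}, expected {(q, self.card)}"
            )
        if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError(f"CPT rows for {self.node} do not sum to 1")
        object.__setattr__(self, "table", table)


@dataclass
class TemporalBayesNet:
    """A DAG plus one CPT per node."""

    structure: DagStructure
    cpts: dict[NodeId, Cpt]
    demographic_schema: dict[str, tuple[str, ...]] = field(default_factory=dict)
    condition_names: tuple[str, ...] = ()
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.structure.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for {node}")
            if self.cpts[node].parents != self.structure.parents(node):
                raise ValueError(f"CPT parents for {node} do not match the structure")

    def card(self, node: NodeId) -> int:
        return self.cpts[node].card

    @property
    def nodes(self) -> tuple[NodeId, ...]:
        return tuple(sorted(self.structure.nodes))


# -- fitting -----------------------------------------------------------------

def _node_column(cohort: LongitudinalCohort, node: NodeId, demo_codes: np.ndarray) -> np.ndarray:
    if node.kind == "condition":
        return cohort.condition_values(node.slice, node.name)
    if node.kind == "demographic":
        j = cohort.demographic_vars.index(node.name)
        return demo_codes[:, j]
    raise ValueError(f"node {node} has no data column")


def _node_card(node: NodeId, schema: Mapping[str, Sequence[str]]) -> int:
    return 2 if node.kind == "condition" else len(schema[node.name])


def fit_cpts(
    dag: DagStructure, cohort: LongitudinalCohort, alpha: float = 1.0
) -> TemporalBayesNet:
    """Estimate every CPT from the cohort.

    ``alpha`` is the per-cell Dirichlet pseudo-count; ``alpha = 0`` gives the
    MLE with a uniform fallback for unobserved parent configurations.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    demo_codes = cohort.demographic_codes()
    schema = cohort.demographic_schema
    cpts: dict[NodeId, Cpt] = {}
    for node in sorted(dag.nodes):
        parents = dag.parents(node)
        card = _node_card(node, schema)
        parent_cards = tuple(_node_card(p, schema) for p in parents)
        q = int(np.prod(parent_cards)) if parents else 1
        child = _node_column(cohort, node, demo_codes)
        if parents:
            cols = [_node_column(cohort, p, demo_codes) for p in parents]
            config = np.ravel_multi_index(cols, parent_cards)
        else:
            config = np.zeros(cohort.n_patients, dtype=np.int64)
        counts = np.bincount(config * card + child, minlength=q * card).reshape(q, card)
        totals = counts.sum(axis=1, keepdims=True)
        if alpha > 0:
            table = (counts + alpha) / (totals + alpha * card)
        else:
            unseen = totals[:, 0] == 0
            if unseen.any():
                logger.warning(
                    "%d unobserved parent configuration(s) for %s at alpha=0; "
                    "using uniform rows",
                    int(unseen.sum()),
                    node,
                )
            safe = np.where(totals == 0, 1, totals)
            table = counts / safe
            table[unseen] = 1.0 / card
        cpts[node] = Cpt(node, parents, parent_cards, card, table, alpha)
    return TemporalBayesNet(
        structure=dag.copy(),
        cpts=cpts,
        demographic_schema={k: tuple(v) for k, v in schema.items()},
        condition_names=cohort.condition_names,
        fit_meta={"n": cohort.n_patients, "alpha": alpha},
    )


def profile_evidence(
    net: TemporalBayesNet, profile: Mapping[str, str]
) -> dict[NodeId, int]:
    """Evidence dict for a demographic profile given as level strings."""
    evidence: dict[NodeId, int] = {}
    for var, level in profile.items():
        levels = net.demographic_schema[var]
        evidence[demographic_node(var)] = levels.index(level)
    return evidence


# -- joint probability ---------------------------------------------------------

def joint_probability(net: TemporalBayesNet, assignment: Mapping[NodeId, int]) -> float:
    """Probability of one full assignment: the product of CPT entries."""
    if set(assignment) != set(net.structure.nodes):
        raise ValueError("assignment must cover every node exactly")
    prob = 1.0
    for node, cpt in net.cpts.items():
        if cpt.parents:
            row = int(
                np.ravel_multi_index(
                    [assignment[p] for p in cpt.parents], cpt.parent_cards
                )
            )
        else:
            row = 0
        prob *= float(cpt.table[row, assignment[node]])
    return prob


# -- variable elimination -------------------------------------------------------

class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple[int, ...], table: np.ndarray) -> None:
        self.vars = vars
        self.table = table


def _factor_product(a: _Factor, b: _Factor) -> _Factor:
    out_vars = tuple(sorted(set(a.vars) | set(b.vars)))
    index = {v: i for i, v in enumerate(out_vars)}

    def expand(f: _Factor, cards: list[int]) -> np.ndarray:
        shape = [1] * len(out_vars)
        for v, size in zip(f.vars, f.table.shape):
            shape[index[v]] = size
            cards[index[v]] = size
        axes = sorted(range(len(f.vars)), key=lambda i: index[f.vars[i]])
        return np.transpose(f.table, axes).reshape(shape)

    cards = [1] * len(out_vars)
    table = expand(a, cards) * expand(b, cards)
    return _Factor(out_vars, table)


def _sum_out(f: _Factor, var: int) -> _Factor:
    axis = f.vars.index(var)
    return _Factor(tuple(v for v in f.vars if v != var), f.table.sum(axis=axis))


def _relevant_nodes(
    net: TemporalBayesNet, query: Iterable[NodeId]
) -> set[NodeId]:
    """Query nodes plus all their ancestors (barren-node pruning)."""
    keep: set[NodeId] = set()
    stack = list(query)
    while stack:
        node = stack.pop()
        if node in keep:
            continue
        keep.add(node)
        stack.extend(net.structure.parents(node))
    return keep


def _build_factors(
    net: TemporalBayesNet,
    nodes: Sequence[NodeId],
    evidence: Mapping[NodeId, int],
) -> tuple[list[_Factor], dict[NodeId, int]]:
    node_ix = {node: i for i, node in enumerate(nodes)}
    factors: list[_Factor] = []
    for node in nodes:
        cpt = net.cpts[node]
        scope = list(cpt.parents) + [node]
        table = cpt.table.reshape(tuple(cpt.parent_cards) + (cpt.card,))
        # reduce on evidence and sort axes into node-index order
        keep_vars: list[int] = []
        slicer: list[object] = []
        for member in scope:
            if member in evidence:
                slicer.append(int(evidence[member]))
            else:
                slicer.append(slice(None))
                keep_vars.append(node_ix[member])
        table = table[tuple(slicer)]
        order = np.argsort(keep_vars, kind="stable")
        table = np.transpose(table, order) if table.ndim > 1 else table
        factors.append(_Factor(tuple(sorted(keep_vars)), np.asarray(table, dtype=float)))
    return factors, node_ix


def _min_fill_order(factors: list[_Factor], eliminate: set[int]) -> list[int]:
    adjacency: dict[int, set[int]] = {}
    for f in factors:
        for v in f.vars:
            adjacency.setdefault(v, set()).update(set(f.vars) - {v})
    order: list[int] = []
    remaining = set(eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = adjacency.get(v, set()) - {v}
            fill = sum(
                1
                for a, b in itertools.combinations(sorted(nbrs), 2)
                if b not in adjacency.get(a, set())
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        remaining.discard(best)
        nbrs = adjacency.pop(best, set()) - {best}
        for a in nbrs:
            adjacency[a].discard(best)
            adjacency[a].update(nbrs - {a})
    return order


def posterior_joint(
    net: TemporalBayesNet,
    evidence: Mapping[NodeId, int],
    targets: Sequence[NodeId],
) -> tuple[tuple[NodeId, ...], np.ndarray]:
    """Exact joint posterior over ``targets`` given ``evidence``.

    Returns the target nodes in sorted order together with the normalised
    probability array (one axis per target). Raises :class:`ZeroEvidenceError`
    if the evidence has probability zero under the model.
    """
    targets = tuple(sorted(targets))
    if not targets:
        raise ValueError("need at least one target node")
    overlap = set(targets) & set(evidence)
    if overlap:
        raise ValueError(f"targets overlap evidence: {sorted(overlap)}")
    for node in itertools.chain(targets, evidence):
        if node not in net.structure.nodes:
            raise ValueError(f"unknown node {node}")

    relevant = sorted(_relevant_nodes(net, set(targets) | set(evidence)))
    factors, node_ix = _build_factors(net, relevant, evidence)
    target_ix = {node_ix[t] for t in targets}
    eliminate = {node_ix[n] for n in relevant if n not in evidence} - target_ix

    for var in _min_fill_order(factors, eliminate):
        bucket = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        prod = bucket[0]
        for f in bucket[1:]:
            prod = _factor_product(prod, f)
        factors.append(_sum_out(prod, var))

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _factor_product(result, f)
    z = float(result.table.sum())
    if z <= 0.0:
        raise ZeroEvidenceError("evidence has probability zero under the model")
    table = result.table / z
    # result.vars is sorted by node index, which matches sorted(targets)
    return targets, np.asarray(table, dtype=float)


def predictive_marginals(
    net: TemporalBayesNet,
    evidence: Mapping[NodeId, int],
    targets: Sequence[NodeId],
) -> dict[NodeId, float]:
    """P(target = 1 | evidence) for each binary target, by variable elimination."""
    out: dict[NodeId, float] = {}
    for target in targets:
        _, table = posterior_joint(net, evidence, [target])
        out[target] = float(table[1])
    return out


def brute_force_marginals(
    net: TemporalBayesNet,
    evidence: Mapping[NodeId, int],
    targets: Sequence[NodeId],
) -> dict[NodeId, float]:
    """Oracle with the :func:`predictive_marginals` contract, by full enumeration."""
    nodes = net.nodes
    if len(nodes) > 22:
        raise ValueError("brute force limited to 22 nodes")
    overlap = set(targets) & set(evidence)
    if overlap:
        raise ValueError(f"targets overlap evidence: {sorted(overlap)}")
    cards = [net.card(n) for n in nodes]
    z = 0.0
    acc = {t: 0.0 for t in targets}
    for states in itertools.product(*(range(c) for c in cards)):
        assignment = dict(zip(nodes, states))
        if any(assignment[n] != v for n, v in evidence.items()):
            continue
        p = joint_probability(net, assignment)
        z += p
        for t in targets:
            if assignment[t] == 1:
                acc[t] += p
    if z <= 0.0:
        raise ZeroEvidenceError("evidence has probability zero under the model")
    return {t: acc[t] / z for t in targets}


# -- state-transition tables ------------------------------------------------------

def transition_table(
    net: TemporalBayesNet,
    profile: Mapping[str, str],
    from_year: int,
    condition_names: Sequence[str],
) -> pd.DataFrame:
    """State-to-state transition probabilities for one demographic profile.

    Rows are year-``from_year`` comorbidity state codes, columns the codes at
    the following year; entry (s, s') is P(state_{t+1} = s' | state_t = s,
    profile), computed by exact inference with the full row state and profile
    as evidence. ``from_year`` is 1-based. Rows whose state has probability
    zero under the model are filled with NaN and listed in
    ``result.attrs["zero_probability_states"]``.
    """
    t = from_year - 1
    T = max(n.slice for n in net.structure.condition_nodes) + 1
    if not 0 <= t < T - 1:
        raise ValueError(f"from_year {from_year} has no following year")
    codes = all_state_codes(condition_names)
    digit_map = default_digit_map(condition_names)
    evidence_profile = profile_evidence(net, profile)
    targets = [condition_node(c, t + 1) for c in condition_names]
    rows = []
    flagged = []
    for code in codes:
        flags = decode_state(code, digit_map, condition_names)
        evidence = dict(evidence_profile)
        for c, f in zip(condition_names, flags):
            evidence[condition_node(c, t)] = int(f)
        try:
            tnodes, table = posterior_joint(net, evidence, targets)
        except ZeroEvidenceError:
            rows.append(np.full(len(codes), np.nan))
            flagged.append(code)
            continue
        # re-order axes from sorted(targets) to condition_names order
        axis_of = {node: i for i, node in enumerate(tnodes)}
        perm = [axis_of[condition_node(c, t + 1)] for c in condition_names]
        joint = np.transpose(table, perm)
        row = np.empty(len(codes))
        for j, col_code in enumerate(codes):
            col_flags = decode_state(col_code, digit_map, condition_names)
            row[j] = joint[tuple(int(f) for f in col_flags)]
        rows.append(row)
    result = pd.DataFrame(rows, index=pd.Index(codes, name=f"year_{from_year}"),
                          columns=pd.Index(codes, name=f"year_{from_year + 1}"))
    result.attrs["zero_probability_states"] = flagged
    return result


# -- JSON serialisation -----------------------------------------------------------

def _node_to_obj(node: NodeId) -> dict:
    return {"name": node.name, "slice": node.slice, "kind": node.kind}


def _node_from_obj(obj: Mapping) -> NodeId:
    return NodeId(name=obj["name"], slice=obj["slice"], kind=obj["kind"])


def save_network(net: TemporalBayesNet, dest) -> None:
    """Serialise a fitted network (structure plus CPT rows) as JSON."""
    import json

    payload = {
        "condition_names": list(net.condition_names),
        "demographic_schema": {k: list(v) for k, v in net.demographic_schema.items()},
        "fit_meta": {k: v for k, v in net.fit_meta.items() if not callable(v)},
        "nodes": [_node_to_obj(n) for n in net.nodes],
        "cpts": [
            {
                "node": _node_to_obj(cpt.node),
                "parents": [_node_to_obj(p) for p in cpt.parents],
                "parent_cards": list(cpt.parent_cards),
                "card": cpt.card,
                "alpha": cpt.alpha,
                "table": cpt.table.tolist(),
            }
            for _, cpt in sorted(net.cpts.items())
        ],
    }
    if isinstance(dest, (str, bytes)):
        with open(dest, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        json.dump(payload, dest, indent=1)


def load_network(source) -> TemporalBayesNet:
    """Read a network written by :func:`save_network`."""
    import json

    if isinstance(source, (str, bytes)):
        with open(source) as fh:
            payload = json.load(fh)
    else:
        payload = json.load(source)
    nodes = [_node_from_obj(o) for o in payload["nodes"]]
    cpts: dict[NodeId, Cpt] = {}
    edges = []
    for entry in payload["cpts"]:
        node = _node_from_obj(entry["node"])
        parents = tuple(_node_from_obj(p) for p in entry["parents"])
        cpts[node] = Cpt(
            node,
            parents,
            tuple(entry["parent_cards"]),
            int(entry["card"]),
            np.asarray(entry["table"], dtype=float),
            float(entry["alpha"]),
        )
        edges.extend((p, node) for p in parents)
    return TemporalBayesNet(
        structure=DagStructure(nodes=nodes, edges=edges),
        cpts=cpts,
        demographic_schema={k: tuple(v) for k, v in payload["demographic_schema"].items()},
        condition_names=tuple(payload["condition_names"]),
        fit_meta=dict(payload["fit_meta"]),
    )
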