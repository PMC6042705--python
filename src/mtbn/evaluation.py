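"""Cross-validated predictive evaluation and confusion-matrix metric panels.

The protocol: k-fold patient-level cross-validation; per fold, the network
structure is (optionally re-)learned and its parameters fitted on the training
patients, and each held-out patient's probability of a future diagnosis is
computed given the condition flags of the evidence years plus the patient's
demographic profile. Held-out scores are pooled over folds and summarised as
the area under the ROC curve per (condition, target year), and thresholded at
50% into confusion matrices with the standard diagnostic-test metric panel
(sensitivity, specificity, predictive values, likelihood ratios, diagnostic
odds ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import LongitudinalCohort
from .network import fit_cpts, posterior_joint
from .structure import (
    DagStructure,
    NodeId,
    add_demographic_level,
    condition_node,
    demographic_node,
    learn_structure,
)

__all__ = [
    "ConfusionCells",
    "MetricReport",
    "CvAucResult",
    "kfold_partition",
    "roc_auc",
    "score_patients",
    "cross_validated_auc",
    "confusion_cells",
    "confusion_metrics",
]


# -- folds and AUC ------------------------------------------------------------

def kfold_partition(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint, seeded, near-equal-size index folds covering range(n)."""
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} patients")
    if k < 1:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann–Whitney form with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# -- model scoring -------------------------------------------------------------

def _evidence_nodes(
    cohort: LongitudinalCohort, evidence_years: Sequence[int]
) -> list[NodeId]:
    nodes = [
        condition_node(c, y - 1)
        for y in evidence_years
        for c in cohort.condition_names
    ]
    nodes += [demographic_node(v) for v in cohort.demographic_vars]
    return nodes


def score_patients(
    net,
    cohort: LongitudinalCohort,
    evidence_years: Sequence[int],
    target_years: Sequence[int],
) -> pd.DataFrame:
    """Per-patient posterior P(condition = 1 | evidence) for each target node.

    The evidence for each patient is every condition flag of the evidence
    years plus the full demographic profile. Patients sharing an evidence
    configuration share one exact-inference call. Years are 1-based. Returns a
    long DataFrame with columns patient_id, condition, target_year, score,
    label.
    """
    evid_nodes = _evidence_nodes(cohort, evidence_years)
    targets = [
        condition_node(c, y - 1)
        for y in target_years
        for c in cohort.condition_names
    ]
    demo_codes = cohort.demographic_codes()
    columns = []
    for node in evid_nodes:
        if node.kind == "condition":
            columns.append(cohort.condition_values(node.slice, node.name))
        else:
            columns.append(demo_codes[:, cohort.demographic_vars.index(node.name)])
    config = np.stack(columns, axis=1)
    uniq, inverse = np.unique(config, axis=0, return_inverse=True)

    probs = np.empty((len(uniq), len(targets)))
    for i, row in enumerate(uniq):
        evidence = {node: int(v) for node, v in zip(evid_nodes, row)}
        for j, target in enumerate(targets):
            _, table = posterior_joint(net, evidence, [target])
            probs[i, j] = table[1]

    records = []
    for j, target in enumerate(targets):
        labels = cohort.condition_values(target.slice, target.name)
        scores = probs[inverse, j]
        for i, pid in enumerate(cohort.patient_ids):
            records.append(
                (pid, target.name, target.slice + 1, float(scores[i]), int(labels[i]))
            )
    return pd.DataFrame(
        records, columns=["patient_id", "condition", "target_year", "score", "label"]
    )


@dataclass
class CvAucResult:
    """Pooled cross-validated AUC table plus the underlying per-patient scores."""

    auc: pd.DataFrame  # index: condition, columns: target_year; NaN if undefined
    scores: pd.DataFrame  # patient_id, fold, condition, target_year, score, label


def cross_validated_auc(
    cohort: LongitudinalCohort,
    evidence_years: Sequence[int],
    target_years: Sequence[int] | None = None,
    k: int = 10,
    seed: int = 0,
    mode: Literal["unsupervised", "semi_supervised", "supervised"] = "unsupervised",
    expert_ordering=None,
    expert_dag: DagStructure | None = None,
    max_parents: int = 3,
    window: int = 1,
    score: Literal["k2", "bic"] = "k2",
    alpha: float = 1.0,
    retrain_structure: bool = True,
) -> CvAucResult:
    """k-fold cross-validated AUC per (condition, target year).

    Structure (unless ``retrain_structure`` is False) and parameters are
    re-estimated on each fold's training patients; held-out scores are pooled
    across folds before the AUC is computed. Cells whose pooled labels are
    single-class are NaN.
    """
    if not evidence_years:
        raise ValueError("need at least one evidence year")
    last_evidence = max(evidence_years)
    if last_evidence >= cohort.n_years:
        raise ValueError("evidence years must leave at least one target year")
    if target_years is None:
        target_years = list(range(last_evidence + 1, cohort.n_years + 1))
    if min(target_years) <= last_evidence:
        raise ValueError("target years must follow the evidence years")

    folds = kfold_partition(cohort.n_patients, k, seed)
    fixed_dag = None
    if not retrain_structure or mode == "supervised":
        fixed_dag = learn_structure(
            cohort, mode, expert_ordering, expert_dag, max_parents, window, score
        )

    pieces = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(cohort.n_patients), test_idx)
        train, test = cohort.subset(train_idx), cohort.subset(test_idx)
        dag = fixed_dag or learn_structure(
            train, mode, expert_ordering, expert_dag, max_parents, window, score
        )
        net = fit_cpts(add_demographic_level(dag, cohort.demographic_schema), train, alpha)
        frame = score_patients(net, test, evidence_years, target_years)
        frame["fold"] = fold_id
        pieces.append(frame)
    scores = pd.concat(pieces, ignore_index=True)

    auc = pd.DataFrame(
        index=pd.Index(cohort.condition_names, name="condition"),
        columns=pd.Index(sorted(target_years), name="target_year"),
        dtype=float,
    )
    for (cond, year), group in scores.groupby(["condition", "target_year"]):
        labels = group["label"].to_numpy()
        if labels.min() == labels.max():
            auc.loc[cond, year] = math.nan
        else:
            auc.loc[cond, year] = roc_auc(group["score"].to_numpy(), labels)
    return CvAucResult(auc=auc, scores=scores)


# -- confusion matrices ---------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCells:
    """2x2 confusion-matrix counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_cells(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCells:
    """Threshold scores into a confusion matrix; ties (score == threshold) are positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    truth = labels == 1
    return ConfusionCells(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


@dataclass(frozen=True)
class MetricReport:
    """Diagnostic-test metric panel; a field is NaN when its denominator is zero."""

    prevalence: float
    tpr: float
    fnr: float
    fpr: float
    tnr: float
    ppv: float
    fdr: float
    npv: float
    for_: float
    lr_plus: float
    lr_minus: float
    dor: float
    accuracy: float


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(cells: ConfusionCells) -> MetricReport:
    """Standard epidemiological metrics derived from a 2x2 confusion matrix."""
    tp, fn, fp, tn = cells.tp, cells.fn, cells.fp, cells.tn
    tpr = _ratio(tp, tp + fn)
    tnr = _ratio(tn, fp + tn)
    fnr = 1 - tpr if not math.isnan(tpr) else math.nan
    fpr = 1 - tnr if not math.isnan(tnr) else math.nan
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    lr_plus = _ratio(tpr, fpr) if not (math.isnan(tpr) or math.isnan(fpr)) else math.nan
    lr_minus = _ratio(fnr, tnr) if not (math.isnan(fnr) or math.isnan(tnr)) else math.nan
    dor = (
        lr_plus / lr_minus
        if not (math.isnan(lr_plus) or math.isnan(lr_minus)) and lr_minus > 0
        else math.nan
    )
    return MetricReport(
        prevalence=_ratio(tp + fn, cells.total),
        tpr=tpr,
        fnr=fnr,
        fpr=fpr,
        tnr=tnr,
        ppv=ppv,
        fdr=1 - ppv if not math.isnan(ppv) else math.nan,
        npv=npv,
        for_=1 - npv if not math.isnan(npv) else math.nan,
        lr_plus=lr_plus,
        lr_minus=lr_minus,
        dor=dor,
        accuracy=_ratio(tp + tn, cells.total),
    )
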