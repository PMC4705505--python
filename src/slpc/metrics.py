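"""Evaluation of predicted complex sets against a gold standard.

Two complexes A and B match when their neighborhood-affinity score

    NA(A, B) = |A ∩ B|^2 / (|A| * |B|)

is at least a threshold (0.25 by default: half the members of each side
shared). Three families of metrics are derived:

* **F-score** — Ncb gold complexes are matched by some prediction and Ncp
  predictions match some gold complex; precision = Ncp/|P|, recall =
  Ncb/|B|, F their harmonic mean.
* **Geometric accuracy** — with T_ij = |gold_i ∩ pred_j|, clustering-wise
  sensitivity Sn = Σ_i max_j T_ij / Σ_i |gold_i| and positive predictive
  value PPV = Σ_j max_i T_ij / Σ_j T.j; Acc = sqrt(Sn · PPV).
* **MMR** — the NA mass of an assignment between gold and predicted
  complexes divided by the number of gold complexes. Two modes exist
  because the metric's common written form (each gold complex takes its
  best NA, "rowmax") disagrees with its prose definition (a one-to-one
  maximum-weight matching, which penalizes predictions that split a gold
  complex since only one fragment may claim it). The one-to-one
  ``matching`` mode is the default; reports always echo the mode used.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network_io import ComplexSet

__all__ = [
    "EvaluationReport",
    "na_score",
    "match_counts",
    "precision_recall_f",
    "sn_ppv_acc",
    "mmr",
    "evaluate",
]


def na_score(a: frozenset, b: frozenset) -> float:
    """Neighborhood affinity |a∩b|²/(|a|·|b|); symmetric, in [0,1], 1 iff a=b."""
    if not a or not b:
        raise ValueError("NA is undefined for empty sets")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def match_counts(
    pred: ComplexSet, gold: ComplexSet, na_threshold: float = 0.25
) -> tuple[int, int]:
    """(Ncb, Ncp): gold complexes matched by ≥1 prediction and vice versa.

    The threshold comparison is inclusive (NA >= threshold matches).
    """
    if not 0 < na_threshold <= 1:
        raise ValueError("na_threshold must lie in (0, 1]")
    ncb = sum(
        1 for b in gold if any(na_score(p, b) >= na_threshold for p in pred)
    )
    ncp = sum(
        1 for p in pred if any(na_score(p, b) >= na_threshold for b in gold)
    )
    return ncb, ncp


def precision_recall_f(
    pred: ComplexSet, gold: ComplexSet, na_threshold: float = 0.25
) -> tuple[float, float, float]:
    ncb, ncp = match_counts(pred, gold, na_threshold) if len(pred) and len(gold) else (0, 0)
    precision = ncp / len(pred) if len(pred) else 0.0
    recall = ncb / len(gold) if len(gold) else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f


def sn_ppv_acc(pred: ComplexSet, gold: ComplexSet) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, positive predictive value, geometric mean.

    A predicted complex overlapping no gold complex has T.j = 0 and
    contributes 0 to both PPV sums; an empty prediction set yields
    (0, 0, 0).
    """
    if len(gold) == 0:
        raise ValueError("Sn/PPV require a non-empty gold standard")
    if len(pred) == 0:
        return 0.0, 0.0, 0.0
    t = np.array([[len(g & p) for p in pred] for g in gold], dtype=float)
    sn = t.max(axis=1).sum() / sum(len(g) for g in gold)
    tdotj = t.sum(axis=0)
    denom = tdotj.sum()
    ppv = t.max(axis=0).sum() / denom if denom > 0 else 0.0
    return float(sn), float(ppv), float(np.sqrt(sn * ppv))


def mmr(pred: ComplexSet, gold: ComplexSet, mode: str = "matching") -> float:
    """Maximum matching ratio between gold and predicted complexes.

    ``matching``: maximum-weight one-to-one matching on the NA bipartite
    graph, total matched weight / n_gold. ``rowmax``: Σ_i max_j NA / n_gold
    (each gold complex takes its best prediction, predictions may be
    reused). rowmax >= matching always.
    """
    if len(gold) == 0:
        raise ValueError("MMR requires a non-empty gold standard")
    if len(pred) == 0:
        return 0.0
    na = np.array([[na_score(g, p) for p in pred] for g in gold])
    if mode == "rowmax":
        total = na.max(axis=1).sum()
    elif mode == "matching":
        rows, cols = linear_sum_assignment(na, maximize=True)
        total = na[rows, cols].sum()
    else:
        raise ValueError(f"unknown MMR mode {mode!r}")
    return float(total) / len(gold)


@dataclass
class EvaluationReport:
    """All metrics for one predicted-vs-gold comparison."""

    ncb: int
    ncp: int
    precision: float
    recall: float
    f_score: float
    sn: float
    ppv: float
    acc: float
    mmr: float
    n_gold: int
    n_pred: int
    na_threshold: float
    mmr_mode: str

    def to_dict(self) -> dict:
        return asdict(self)

    def pretty(self) -> str:
        lines = [
            f"gold complexes   {self.n_gold}",
            f"predicted        {self.n_pred}",
            f"matched (Ncb)    {self.ncb}",
            f"matched (Ncp)    {self.ncp}",
            f"precision        {self.precision:.4f}",
            f"recall           {self.recall:.4f}",
            f"F-score          {self.f_score:.4f}",
            f"Sn               {self.sn:.4f}",
            f"PPV              {self.ppv:.4f}",
            f"Acc              {self.acc:.4f}",
            f"MMR ({self.mmr_mode:8s}) {self.mmr:.4f}",
        ]
        return "\n".join(lines)


def evaluate(
    pred: ComplexSet,
    gold: ComplexSet,
    na_threshold: float = 0.25,
    mmr_mode: str = "matching",
) -> EvaluationReport:
    """Full evaluation report; gold must be non-empty."""
    if len(gold) == 0:
        raise ValueError("evaluation requires a non-empty gold standard")
    ncb, ncp = match_counts(pred, gold, na_threshold) if len(pred) else (0, 0)
    precision, recall, f = precision_recall_f(pred, gold, na_threshold)
    sn, ppv, acc = sn_ppv_acc(pred, gold)
    return EvaluationReport(
        ncb=ncb,
        ncp=ncp,
        precision=precision,
        recall=recall,
        f_score=f,
        sn=sn,
        ppv=ppv,
        acc=acc,
        mmr=mmr(pred, gold, mmr_mode),
        n_gold=len(gold),
        n_pred=len(pred),
        na_threshold=na_threshold,
        mmr_mode=mmr_mode,
    )
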