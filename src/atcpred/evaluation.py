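"""Jackknife cross-validation and ordered-prediction accuracy measures.

Each drug in the benchmark is singled out in turn and predicted by the
model "trained" on all remaining drugs (leave-one-out).  Because the
predictor is nonparametric — per-class maxima over a score table — leaving
a drug out simply means its own class memberships contribute no evidence
to its prediction.

Accuracy is measured on the ordered ranking:

* ``CP_j`` — number of drugs whose j-th ranked class is one of their true
  classes; ``AC_j = CP_j / N``.
* ``AN`` — mean number of true classes per query drug; equals the
  virtual/structural count ratio of the evaluated subset.
* ``m`` — the smallest integer >= AN: how many leading ranks to examine.
* ``L_m`` — fraction of all true (drug, class) memberships recovered
  within each drug's first m ranked classes.

These satisfy the exact identity ``N * AN * L_m = sum_{j<=m} CP_j`` (both
sides count the same (drug, hit-order) pairs).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .atc import N_CLASSES, DrugLabelSet, LabelTable
from .predictor import (
    FALLBACK_MODES,
    RankedPrediction,
    _likelihoods,
    _predict_integrated,
    rank_classes,
)
from .scores import ScoreTable

__all__ = [
    "MultiplicityHistogram",
    "multiplicity_histogram",
    "virtual_count",
    "average_class_count",
    "choose_m",
    "compute_cp",
    "coverage_lm",
    "lm_from_order_accuracies",
    "EvaluationReport",
    "jackknife_evaluate",
    "EVALUATION_METHODS",
]

EVALUATION_METHODS = ("interaction", "similarity", "integrated")


@dataclass(frozen=True)
class MultiplicityHistogram:
    """Distribution of class multiplicities: counts[k] drugs hold exactly
    k classes."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for k, c in self.counts.items():
            if not (1 <= int(k) <= N_CLASSES):
                raise ValueError(f"multiplicity {k!r} outside 1..{N_CLASSES}")
            if c < 0:
                raise ValueError(f"negative count {c!r} for multiplicity {k}")
            if c:
                clean[int(k)] = int(c)
        object.__setattr__(self, "counts", clean)

    @property
    def structural_count(self) -> int:
        """Number of distinct drugs."""
        return sum(self.counts.values())

    @property
    def virtual_count(self) -> int:
        """Number of (drug, class) memberships: sum over k of k * counts[k]."""
        return sum(k * c for k, c in self.counts.items())


def multiplicity_histogram(labels: LabelTable) -> MultiplicityHistogram:
    """Histogram of class multiplicities of a label table."""
    return MultiplicityHistogram(labels.multiplicities())


def virtual_count(hist: MultiplicityHistogram | Mapping[int, int]) -> int:
    """Total virtual samples of a multiplicity histogram.

    A drug in k classes counts k times, so the virtual total generally
    exceeds the structural (distinct-drug) total.
    """
    if not isinstance(hist, MultiplicityHistogram):
        hist = MultiplicityHistogram(hist)
    return hist.virtual_count


def average_class_count(
    labels: LabelTable | Iterable[DrugLabelSet],
) -> float:
    """AN: the mean number of true classes per drug.

    Equals virtual count / structural count of the same subset.
    """
    if isinstance(labels, LabelTable):
        records: Sequence[DrugLabelSet] = list(labels.records.values())
    else:
        records = list(labels)
    if not records:
        raise ValueError("cannot compute the average class count of an empty set")
    return sum(r.multiplicity for r in records) / len(records)


def choose_m(an: float) -> int:
    """Number of leading prediction orders to examine: the smallest
    integer >= AN (so AN = 1.24 gives m = 2, and an exactly integral AN
    gives itself)."""
    if an < 1:
        raise ValueError(f"AN must be >= 1 (every drug has at least one class), got {an!r}")
    return max(1, math.ceil(an))


def compute_cp(
    predictions: Sequence[RankedPrediction],
    labels: LabelTable,
    length: int | None = None,
) -> list[int]:
    """Per-order hit counts CP_j.

    ``CP[j-1]`` counts the drugs whose j-th ranked class is one of their
    true classes.  Rankings shorter than ``length`` contribute nothing at
    the missing orders.
    """
    if length is None:
        length = max((len(p.order) for p in predictions), default=0)
    cp = [0] * length
    for pred in predictions:
        rec = labels.get(pred.drug_id)
        if rec is None:
            raise ValueError(f"prediction for unknown drug {pred.drug_id!r}")
        for j, cls in enumerate(pred.order[:length]):
            if cls in rec.classes:
                cp[j] += 1
    return cp


def coverage_lm(
    predictions: Sequence[RankedPrediction],
    labels: LabelTable,
    m: int,
) -> float:
    """L_m: the proportion of all true classes recovered within the first
    m ranked classes, summed over drugs: (sum_i P_{i,m}) / (sum_i T_i)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m!r}")
    hits = 0
    total = 0
    for pred in predictions:
        rec = labels.get(pred.drug_id)
        if rec is None:
            raise ValueError(f"prediction for unknown drug {pred.drug_id!r}")
        hits += len(rec.classes.intersection(pred.order[:m]))
        total += rec.multiplicity
    if total == 0:
        raise ValueError("no true classes to cover (empty prediction set)")
    return hits / total


def lm_from_order_accuracies(
    accuracies: Sequence[float], an: float, m: int | None = None
) -> float:
    """Reconstruct L_m from per-order accuracies: (AC_1 + ... + AC_m) / AN.

    This is the identity L_m = sum_{j<=m} CP_j / (N * AN) with AC_j =
    CP_j / N; it lets the coverage statistic be recomputed from a printed
    per-order accuracy table and the exact AN of the same drug set.
    """
    if an < 1:
        raise ValueError(f"AN must be >= 1, got {an!r}")
    if m is None:
        m = len(accuracies)
    if not (1 <= m <= len(accuracies)):
        raise ValueError(f"m={m} outside 1..{len(accuracies)}")
    return sum(accuracies[:m]) / an


@dataclass
class EvaluationReport:
    """Aggregate result of one jackknife run."""

    n_queries: int
    cp: list[int]
    ac: list[float]
    an: float
    m: int
    l_m: float
    method_breakdown: dict[str, int]
    cp_by_method: dict[str, list[int]]
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "cp": list(self.cp),
            "ac": list(self.ac),
            "an": self.an,
            "m": self.m,
            "l_m": self.l_m,
            "method_breakdown": dict(self.method_breakdown),
            "cp_by_method": {k: list(v) for k, v in self.cp_by_method.items()},
            "settings": dict(self.settings),
        }


def _jackknife_predict_one(
    drug_id: str,
    labels: LabelTable,
    q_table: ScoreTable | None,
    s_table: ScoreTable | None,
    method: str,
    fallback: str,
    include_zero_classes: bool,
) -> RankedPrediction:
    exclude = frozenset((drug_id,))
    if method == "integrated":
        assert q_table is not None and s_table is not None
        return _predict_integrated(
            drug_id, labels, q_table, s_table, fallback, include_zero_classes, exclude
        )
    table = q_table if method == "interaction" else s_table
    assert table is not None
    lv = _likelihoods(drug_id, labels, table, exclude)
    return rank_classes(
        lv,
        drug_id=drug_id,
        include_zero_classes=include_zero_classes,
        method_used="none" if lv.is_trivial else table.kind,
    )


def jackknife_evaluate(
    labels: LabelTable,
    q_table: ScoreTable | None = None,
    s_table: ScoreTable | None = None,
    *,
    method: str = "integrated",
    fallback: str = "per_query",
    include_zero_classes: bool = True,
) -> tuple[list[RankedPrediction], EvaluationReport]:
    """Leave-one-out evaluation of a prediction method over a benchmark.

    Every drug is predicted with its entire record (all class memberships)
    removed from the training table; the run is fully deterministic.
    Returns the per-drug rankings in sorted drug-id order together with the
    aggregated :class:`EvaluationReport`.  AN, m and L_m are computed on
    the same drug subset being evaluated.
    """
    if method not in EVALUATION_METHODS:
        raise ValueError(f"method must be one of {EVALUATION_METHODS}, got {method!r}")
    if fallback not in FALLBACK_MODES:
        raise ValueError(f"fallback must be one of {FALLBACK_MODES}, got {fallback!r}")
    if len(labels) < 2:
        raise ValueError("jackknife evaluation needs at least 2 drugs")
    if method in ("interaction", "integrated") and q_table is None:
        raise ValueError(f"method={method!r} requires an interaction score table")
    if method in ("similarity", "integrated") and s_table is None:
        raise ValueError(f"method={method!r} requires a similarity score table")

    predictions: list[RankedPrediction] = []
    for drug_id in labels.drug_ids():
        pred = _jackknife_predict_one(
            drug_id, labels, q_table, s_table, method, fallback, include_zero_classes
        )
        # Jackknife hygiene: the query's own record must not have contributed.
        assert pred.drug_id == drug_id
        predictions.append(pred)

    n = len(predictions)
    length = max(len(p.order) for p in predictions)
    cp = compute_cp(predictions, labels, length)
    an = average_class_count(labels)
    m = choose_m(an)
    l_m = coverage_lm(predictions, labels, min(m, length) if length else m)
    breakdown = Counter(p.method_used for p in predictions)
    cp_by_method = {
        meth: compute_cp([p for p in predictions if p.method_used == meth], labels, length)
        for meth in sorted(breakdown)
    }
    report = EvaluationReport(
        n_queries=n,
        cp=cp,
        ac=[c / n for c in cp],
        an=an,
        m=m,
        l_m=l_m,
        method_breakdown=dict(breakdown),
        cp_by_method=cp_by_method,
        settings={
            "method": method,
            "fallback": fallback,
            "include_zero_classes": include_zero_classes,
        },
    )
    return predictions, report
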