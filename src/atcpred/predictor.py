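"""Per-class likelihoods and class ranking.

The predictor is a guilt-by-association rule: the likelihood that a query
drug belongs to class C_j is the *maximum* pairwise score between the query
and any training drug that holds class j.  The same rule is applied to two
kinds of evidence — interaction confidence scores and structural similarity
scores — and the integrated method chains them: interactions first, and the
similarity table only as a fallback when every interaction-based likelihood
is zero (the "trivial outcome": the query has no interaction record against
the training set).

Classes are ranked by descending likelihood; ties are broken by ascending
class index so that every ranking is a deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet

from .atc import N_CLASSES, LabelTable
from .scores import ScoreTable

__all__ = [
    "LikelihoodVector",
    "RankedPrediction",
    "class_likelihoods",
    "rank_classes",
    "predict",
    "predict_integrated",
    "FALLBACK_MODES",
]

#: Fallback semantics for the integrated method.  ``per_query`` applies the
#: trivial-outcome test literally (route to similarity iff all 14
#: interaction likelihoods are zero); ``dataset`` routes a query to
#: similarity iff it has no interaction record at all, mirroring a
#: dataset-level split into drugs with / without interaction information.
FALLBACK_MODES = ("per_query", "dataset")


@dataclass(frozen=True)
class LikelihoodVector:
    """The 14 per-class likelihoods for one query.

    ``values[j-1]`` is the maximum score between the query and the training
    drugs of class j (0 when no such drug has a positive score).
    """

    values: tuple[float, ...]
    source_kind: str

    def __post_init__(self) -> None:
        if len(self.values) != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} values, got {len(self.values)}")
        if any(v < 0 for v in self.values):
            raise ValueError("likelihoods must be nonnegative")

    def __getitem__(self, class_index: int) -> float:
        """Likelihood of a 1-based class index."""
        if not (1 <= class_index <= N_CLASSES):
            raise IndexError(f"class index {class_index} outside 1..{N_CLASSES}")
        return self.values[class_index - 1]

    @property
    def is_trivial(self) -> bool:
        """True when every class likelihood is zero (no evidence at all)."""
        return all(v == 0 for v in self.values)


_TRIVIAL_VALUES = tuple([0] * N_CLASSES)


@dataclass(frozen=True)
class RankedPrediction:
    """Classes for one query, ordered by descending likelihood.

    ``order`` holds 1-based class indices; ``scores`` the likelihood at
    each ranked position (non-increasing).  ``method_used`` records which
    evidence produced the ranking: ``interaction``, ``similarity``, or
    ``none`` when no evidence existed and the ranking is the pure
    index-order tie-break.
    """

    drug_id: str
    order: tuple[int, ...]
    scores: tuple[float, ...]
    method_used: str

    def __post_init__(self) -> None:
        if len(self.order) != len(self.scores):
            raise ValueError("order and scores must have equal length")
        if any(x > y for x, y in zip(self.scores[1:], self.scores)):
            raise ValueError("scores must be non-increasing along the ranking")

    def rank_of(self, class_index: int) -> int | None:
        """1-based position of a class in the ranking, or None if absent."""
        try:
            return self.order.index(class_index) + 1
        except ValueError:
            return None


def _likelihoods(
    query_id: str,
    labels: LabelTable,
    scores: ScoreTable,
    exclude: AbstractSet[str] = frozenset(),
) -> LikelihoodVector:
    """Maximum-score-per-class over the query's stored partners.

    ``exclude`` lets the jackknife driver mask the query's own record
    without copying the label table; partners outside ``labels`` contribute
    nothing.
    """
    vals = [0] * N_CLASSES
    for partner, s in scores.neighbors(query_id).items():
        if partner == query_id or partner in exclude:
            continue
        rec = labels.get(partner)
        if rec is None:
            continue
        for j in rec.classes:
            if s > vals[j - 1]:
                vals[j - 1] = s
    return LikelihoodVector(tuple(vals), scores.kind)


def class_likelihoods(query_id: str, labels: LabelTable, scores: ScoreTable) -> LikelihoodVector:
    """Compute the query's 14 per-class likelihoods against a training table.

    The query must not itself be a training drug (the caller removes it;
    the jackknife driver guarantees this), otherwise its own memberships
    would leak into the evidence.
    """
    if len(labels) == 0:
        raise ValueError("training label table is empty")
    if query_id in labels:
        raise ValueError(
            f"query {query_id!r} is present in the training labels; "
            "remove it before predicting (self-evidence leak)"
        )
    return _likelihoods(query_id, labels, scores)


def rank_classes(
    lv: LikelihoodVector,
    *,
    drug_id: str = "",
    include_zero_classes: bool = True,
    method_used: str | None = None,
) -> RankedPrediction:
    """Order classes by descending likelihood, ties by ascending index.

    With ``include_zero_classes`` (default) all 14 classes appear and
    zero-likelihood classes trail in index order; otherwise only classes
    with positive likelihood are ranked and the ranking may be shorter.
    """
    indices = [
        j for j in range(1, N_CLASSES + 1) if include_zero_classes or lv[j] > 0
    ]
    indices.sort(key=lambda j: (-lv[j], j))
    return RankedPrediction(
        drug_id=drug_id,
        order=tuple(indices),
        scores=tuple(lv[j] for j in indices),
        method_used=lv.source_kind if method_used is None else method_used,
    )


def predict(
    query_id: str,
    labels: LabelTable,
    scores: ScoreTable,
    *,
    include_zero_classes: bool = True,
) -> RankedPrediction:
    """Single-evidence prediction: rank classes by one score table.

    When the likelihood vector is trivial the result is the all-tie
    index-order ranking with ``method_used="none"``.
    """
    lv = class_likelihoods(query_id, labels, scores)
    method = "none" if lv.is_trivial else scores.kind
    return rank_classes(
        lv, drug_id=query_id, include_zero_classes=include_zero_classes, method_used=method
    )


def _predict_integrated(
    query_id: str,
    labels: LabelTable,
    q_table: ScoreTable,
    s_table: ScoreTable,
    fallback: str,
    include_zero_classes: bool,
    exclude: AbstractSet[str] = frozenset(),
) -> RankedPrediction:
    if fallback not in FALLBACK_MODES:
        raise ValueError(f"fallback must be one of {FALLBACK_MODES}, got {fallback!r}")
    if q_table.kind != "interaction":
        raise ValueError("q_table must be an interaction ScoreTable")
    if s_table.kind != "similarity":
        raise ValueError("s_table must be a similarity ScoreTable")

    kw = dict(drug_id=query_id, include_zero_classes=include_zero_classes)

    if fallback == "dataset" and query_id in q_table.covered_ids:
        # Dataset-split semantics: any interaction record at all keeps the
        # query on the interaction route, even if its likelihoods are zero.
        lv_q = _likelihoods(query_id, labels, q_table, exclude)
        return rank_classes(lv_q, method_used="interaction", **kw)

    if fallback == "per_query":
        lv_q = _likelihoods(query_id, labels, q_table, exclude)
        if not lv_q.is_trivial:
            return rank_classes(lv_q, method_used="interaction", **kw)

    lv_s = _likelihoods(query_id, labels, s_table, exclude)
    if not lv_s.is_trivial:
        return rank_classes(lv_s, method_used="similarity", **kw)
    return rank_classes(
        LikelihoodVector(_TRIVIAL_VALUES, s_table.kind), method_used="none", **kw
    )


def predict_integrated(
    query_id: str,
    labels: LabelTable,
    q_table: ScoreTable,
    s_table: ScoreTable,
    *,
    fallback: str = "per_query",
    include_zero_classes: bool = True,
) -> RankedPrediction:
    """Two-step integrated prediction.

    Step 1 applies the interaction-based likelihoods.  Step 2 falls back to
    the similarity-based likelihoods when step 1 yields the trivial
    all-zero outcome (``fallback="per_query"``, the default) or when the
    query has no interaction record at all (``fallback="dataset"``).  The
    two score scales are never mixed numerically — integration is purely a
    routing rule.  If both vectors are trivial the all-tie ranking is
    returned with ``method_used="none"``.
    """
    if len(labels) == 0:
        raise ValueError("training label table is empty")
    if query_id in labels:
        raise ValueError(
            f"query {query_id!r} is present in the training labels; "
            "remove it before predicting (self-evidence leak)"
        )
    return _predict_integrated(
        query_id, labels, q_table, s_table, fallback, include_zero_classes
    )
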