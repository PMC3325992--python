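"""Sparse symmetric pairwise score tables.

One container serves both kinds of evidence the predictor consumes:

* ``interaction`` — STITCH-style chemical-chemical interaction confidence
  scores, integers with nominal range 1..1000;
* ``similarity`` — structural similarity scores in (0, 1], e.g. Jaccard
  coefficients on a maximum common subgraph.

The convention throughout is that an absent pair scores exactly 0, so only
positive scores are stored.  Self-pairs are dropped at ingest: a query must
never serve as its own evidence, which keeps the plain prediction path
consistent with the leave-one-out evaluation path.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Mapping

__all__ = ["ScoreTable", "build_score_table", "SCORE_KINDS"]

SCORE_KINDS = ("interaction", "similarity")


class ScoreTable:
    """Symmetric sparse lookup of pair scores with default 0.

    Stored as an adjacency dict-of-dicts; both orientations of every pair
    are present, so neighbour iteration is O(degree).
    """

    def __init__(self, kind: str, adjacency: Mapping[str, Mapping[str, float]]):
        if kind not in SCORE_KINDS:
            raise ValueError(f"kind must be one of {SCORE_KINDS}, got {kind!r}")
        self.kind = kind
        self._adj: dict[str, dict[str, float]] = {
            a: dict(nbrs) for a, nbrs in adjacency.items() if nbrs
        }

    def score(self, a: str, b: str) -> float:
        """Score of the unordered pair (a, b); 0 if absent or a == b."""
        return self._adj.get(a, {}).get(b, 0)

    def neighbors(self, a: str) -> Mapping[str, float]:
        """All partners of ``a`` with their (positive) scores."""
        return self._adj.get(a, {})

    @property
    def covered_ids(self) -> frozenset[str]:
        """Ids appearing in at least one stored entry."""
        return frozenset(self._adj)

    @property
    def n_pairs(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def items(self) -> Iterator[tuple[str, str, float]]:
        """Iterate stored pairs once each, as (a, b, score) with a < b,
        in sorted order (deterministic serialisation order)."""
        for a in sorted(self._adj):
            nbrs = self._adj[a]
            for b in sorted(nbrs):
                if a < b:
                    yield a, b, nbrs[b]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ScoreTable)
            and self.kind == other.kind
            and self._adj == other._adj
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScoreTable(kind={self.kind!r}, {self.n_pairs} pairs, {len(self._adj)} ids)"


def build_score_table(
    kind: str,
    edges: Iterable[tuple[str, str, float]],
    duplicate_policy: str = "max",
) -> ScoreTable:
    """Assemble a :class:`ScoreTable` from an edge list.

    Rules applied at ingest:

    * scores must be nonnegative; similarity scores must not exceed 1;
      interaction scores must be integral;
    * zero-score edges are discarded (zero means "absent");
    * self-pairs are discarded with a warning;
    * when the same unordered pair occurs with different scores,
      ``duplicate_policy`` decides: ``"max"`` (default, order-independent)
      keeps the larger value, ``"error"`` raises.
    """
    if kind not in SCORE_KINDS:
        raise ValueError(f"kind must be one of {SCORE_KINDS}, got {kind!r}")
    if duplicate_policy not in ("max", "error"):
        raise ValueError(f"duplicate_policy must be 'max' or 'error', got {duplicate_policy!r}")

    adj: dict[str, dict[str, float]] = {}
    for a, b, s in edges:
        a = a.strip()
        b = b.strip()
        if not a or not b:
            raise ValueError(f"empty identifier in edge ({a!r}, {b!r})")
        if s < 0:
            raise ValueError(f"negative score {s!r} for pair ({a!r}, {b!r})")
        if kind == "similarity" and s > 1:
            raise ValueError(f"similarity score {s!r} > 1 for pair ({a!r}, {b!r})")
        if kind == "interaction":
            if int(s) != s:
                raise ValueError(f"non-integer interaction score {s!r} for pair ({a!r}, {b!r})")
            s = int(s)
        if a == b:
            warnings.warn(f"ignoring self-pair ({a!r}, {a!r})", stacklevel=2)
            continue
        if s == 0:
            continue
        prev = adj.get(a, {}).get(b)
        if prev is not None and prev != s:
            if duplicate_policy == "error":
                raise ValueError(
                    f"conflicting scores for pair ({a!r}, {b!r}): {prev!r} vs {s!r}"
                )
            s = max(prev, s)
        adj.setdefault(a, {})[b] = s
        adj.setdefault(b, {})[a] = s
    return ScoreTable(kind, adj)
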