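"""Query-answering evaluation with ranking metrics.

The evaluation predicts likely query triplets from entity-pair frequency,
aligns them against a deduplicated ground-truth table, and scores the
alignment with recall, precision, F1, MRR, MAP and nDCG.

Two conventions here are deliberately nonstandard and follow the system
being evaluated rather than the IR textbook:

* **MRR and MAP are normalised by ground-truth size**, not by the number of
  queries.  With hits at ranks 1 and 3 against 202 ground-truth triplets,
  MRR = (1/1 + 1/3) / 202, not (1/1 + 1/3) / 2.  The query-count variants
  are available via ``per_query=True``.
* **The DCG discount is log2(rank) with rank 1 undiscounted** — the gain at
  rank i >= 2 is rel_i / log2(i), so rank 2 is also effectively
  undiscounted (log2(2) = 1).  The common log2(i + 1) discount is available
  via ``discount="log2(i+1)"``.

All metrics are pure functions; reports round half-up to 4 decimal places.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from ._types import Triplet, TripletTable, normalize


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal round-half-up (0.00005 -> 0.0001), as reports print it."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RankedTriplet:
    """A predicted triplet at a 1-based rank with an optional relevance grade."""

    key: tuple[str, str, str]
    rank: int
    relevance: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.relevance < 0:
            raise ValueError("relevance must be >= 0")


@dataclass(frozen=True)
class MetricsReport:
    recall: float
    precision: float
    f1: float
    mrr: float
    map: float
    dcg: float
    idcg: float
    ndcg: float
    n_truth: int
    n_predicted: int
    n_hits: int

    def rounded(self, ndigits: int = 4) -> dict[str, float | int]:
        out: dict[str, float | int] = {}
        for name in ("recall", "precision", "f1", "mrr", "map",
                     "dcg", "idcg", "ndcg"):
            out[name] = round_half_up(getattr(self, name), ndigits)
        out.update(n_truth=self.n_truth, n_predicted=self.n_predicted,
                   n_hits=self.n_hits)
        return out


# ---------------------------------------------------------------------------
# Prediction and alignment


def predict_query_triplets(
    table: TripletTable, k: int, relation: str = "Am"
) -> list[RankedTriplet]:
    """The k most frequent co-occurring entity pairs, cast as query triplets.

    Pairs are unordered; orientation follows the first observed row.  The
    supplied relation (default "Am") replaces the observed relations,
    mimicking a question template.  Ranking is by descending pair frequency
    with lexicographic tie-break; ranks are 1..k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    freq: Counter = Counter()
    orientation: dict[tuple[str, str], tuple[str, str]] = {}
    for t in table:
        if t.subject.is_empty or t.object.is_empty:
            continue
        s, o = t.subject.normalized, t.object.normalized
        pair = (s, o) if s <= o else (o, s)
        freq[pair] += 1
        orientation.setdefault(pair, (s, o))
    ranked = sorted(freq.items(), key=lambda pc: (-pc[1], pc[0]))[:k]
    rel = normalize(relation)
    return [
        RankedTriplet(key=(orientation[p][0], rel, orientation[p][1]), rank=i)
        for i, (p, _) in enumerate(ranked, start=1)
    ]


def align(
    predicted: Sequence[RankedTriplet], truth: TripletTable
) -> list[RankedTriplet]:
    """Predicted items whose normalised key occurs in the truth, ranks kept."""
    truth_keys = set(truth.keys())
    return [p for p in predicted if p.key in truth_keys]


# ---------------------------------------------------------------------------
# Metrics


def recall_precision_f1(
    n_hits: int, n_truth: int, n_predicted: int
) -> tuple[float, float, float]:
    """Hit rate against truth, against predictions, and their harmonic mean."""
    recall = n_hits / n_truth if n_truth else 0.0
    precision = n_hits / n_predicted if n_predicted else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return recall, precision, f1


def mrr_paper(
    hit_ranks: Iterable[int], n_truth: int, *, per_query: bool = False
) -> float:
    """Sum of reciprocal hit ranks over the ground-truth size.

    ``per_query=True`` divides by the number of hits instead (the textbook
    mean-reciprocal-rank over answered queries).
    """
    if n_truth < 1:
        raise ValueError(f"n_truth must be >= 1, got {n_truth}")
    ranks = list(hit_ranks)
    if not ranks:
        return 0.0
    total = sum(1.0 / r for r in ranks)
    return total / (len(ranks) if per_query else n_truth)


def map_paper(
    hits: Iterable[tuple[int, int]], n_truth: int, *, per_query: bool = False
) -> float:
    """Relevance-weighted reciprocal ranks over the ground-truth size.

    ``hits`` are (rank, relevance) pairs.  With all relevances equal to 1
    this reduces to :func:`mrr_paper`.
    """
    if n_truth < 1:
        raise ValueError(f"n_truth must be >= 1, got {n_truth}")
    pairs = list(hits)
    if not pairs:
        return 0.0
    total = sum(rel / rank for rank, rel in pairs)
    return total / (len(pairs) if per_query else n_truth)


def dcg_idcg_ndcg(
    relevances: Sequence[float], *, discount: str = "log2(i)"
) -> tuple[float, float, float]:
    """Discounted cumulative gain of a ranked relevance list.

    With the default discount the gain at rank 1 is undiscounted and at
    rank i >= 2 it is rel_i / log2(i); ``discount="log2(i+1)"`` selects the
    common convention rel_i / log2(i + 1).  IDCG applies the same formula
    to the descending-sorted list; nDCG is DCG/IDCG (0 when IDCG is 0).
    """
    if discount not in ("log2(i)", "log2(i+1)"):
        raise ValueError(f"unknown discount convention {discount!r}")

    def gain(rel: float, rank: int) -> float:
        if discount == "log2(i+1)":
            return rel / math.log2(rank + 1)
        return rel if rank == 1 else rel / math.log2(rank)

    dcg = sum(gain(rel, i) for i, rel in enumerate(relevances, start=1))
    ideal = sorted(relevances, reverse=True)
    idcg = sum(gain(rel, i) for i, rel in enumerate(ideal, start=1))
    ndcg = dcg / idcg if idcg else 0.0
    return dcg, idcg, ndcg


def evaluate(
    predicted: Sequence[RankedTriplet],
    truth: TripletTable,
    relevance_grades: Mapping[tuple[str, str, str], int] | None = None,
) -> MetricsReport:
    """Full alignment + metrics report.

    MAP weights each hit by its relevance grade — taken from
    ``relevance_grades`` when supplied, else from the hit's own
    ``relevance`` field, defaulting to 1.  DCG relevance is binary
    hit/miss over the prediction ranks unless grades are supplied.
    """
    hits = align(predicted, truth)
    n_truth, n_predicted = truth.row_count, len(predicted)
    recall, precision, f1 = recall_precision_f1(len(hits), n_truth, n_predicted)

    if not hits:
        return MetricsReport(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                             n_truth, n_predicted, 0)

    def grade(h: RankedTriplet) -> int:
        if relevance_grades is not None and h.key in relevance_grades:
            return relevance_grades[h.key]
        return h.relevance if h.relevance > 0 else 1

    mrr = mrr_paper((h.rank for h in hits), n_truth)
    mapv = map_paper(((h.rank, grade(h)) for h in hits), n_truth)

    n_slots = max([n_predicted, *[h.rank for h in hits]])
    rel_vector = [0.0] * n_slots
    for h in hits:
        rel_vector[h.rank - 1] = (
            float(relevance_grades[h.key])
            if relevance_grades is not None and h.key in relevance_grades
            else 1.0
        )
    dcg, idcg, ndcg = dcg_idcg_ndcg(rel_vector)

    return MetricsReport(
        recall=recall, precision=precision, f1=f1, mrr=mrr, map=mapv,
        dcg=dcg, idcg=idcg, ndcg=ndcg,
        n_truth=n_truth, n_predicted=n_predicted, n_hits=len(hits),
    )


__all__ = [
    "RankedTriplet",
    "MetricsReport",
    "round_half_up",
    "predict_query_triplets",
    "align",
    "recall_precision_f1",
    "mrr_paper",
    "map_paper",
    "dcg_idcg_ndcg",
    "evaluate",
]
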