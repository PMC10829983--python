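"""Staged refinement of a triplet table.

The cascade mirrors the multi-level design: keyword filtering narrows the
table to the domain of interest, completeness filtering drops triplets with
a missing subject, relation or object, deduplication collapses overlapping
triplets onto a normalised (source, edge, target) key, and an optional
expert-validation pass removes rows a reviewer rejected.  Every stage is
non-increasing in row count and preserves row order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._types import Triplet, TripletTable, normalize
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationDecision:
    """One expert verdict on a normalised triplet key."""

    key: tuple[str, str, str]
    verdict: str  # "approved" | "rejected"
    reviewer: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in ("approved", "rejected"):
            raise ValueError(
                f"verdict must be 'approved' or 'rejected', got {self.verdict!r}"
            )


def _keyword_match(phrase_norm: str, keywords: frozenset[str]) -> bool:
    # a keyword matches when it occurs as a substring of any token of the
    # normalised phrase ("asthma" matches "severe asthma")
    return any(kw in tok for tok in phrase_norm.split() for kw in keywords)


def filter_by_keywords(
    table: TripletTable, keywords: Iterable[str]
) -> TripletTable:
    """Keep rows whose subject or object carries at least one keyword.

    Keywords are normalised before matching; matching is substring-per-token
    on the normalised entity phrases.  An empty keyword set is a
    configuration error (the stage would silently drop everything).
    """
    kw = frozenset(normalize(k) for k in keywords if normalize(k))
    if not kw:
        raise ConfigurationError("keyword filter requires a non-empty keyword set")
    rows = [
        t
        for t in table
        if _keyword_match(t.subject.normalized, kw)
        or _keyword_match(t.object.normalized, kw)
    ]
    return table.with_rows(rows, stage_label="keyword-filtered")


def filter_complete(table: TripletTable) -> TripletTable:
    """Keep only complete triplets (non-empty subject, relation and object)."""
    rows = [t for t in table if t.complete]
    return table.with_rows(rows, stage_label="complete")


def deduplicate(table: TripletTable) -> TripletTable:
    """Collapse overlapping triplets: first occurrence of each key survives.

    The key is the normalised (source, edge, target); idempotent by
    construction.
    """
    seen: set[tuple[str, str, str]] = set()
    rows: list[Triplet] = []
    for t in table:
        if t.key not in seen:
            seen.add(t.key)
            rows.append(t)
    return table.with_rows(rows, stage_label="deduplicated")


def apply_validation(
    table: TripletTable, decisions: Sequence[ValidationDecision]
) -> TripletTable:
    """Drop rows an expert rejected; undecided rows are kept.

    Conflicting verdicts (approve and reject for one key) raise
    :class:`ValidationError` listing the offending keys.
    """
    verdicts: dict[tuple[str, str, str], str] = {}
    conflicts: list[tuple[str, str, str]] = []
    for d in decisions:
        prev = verdicts.get(d.key)
        if prev is not None and prev != d.verdict:
            conflicts.append(d.key)
        verdicts[d.key] = d.verdict
    if conflicts:
        raise ValidationError(
            "conflicting validation verdicts for keys: "
            + ", ".join(repr(k) for k in sorted(set(conflicts)))
        )
    rows = [t for t in table if verdicts.get(t.key) != "rejected"]
    return table.with_rows(rows, stage_label="validated")


def refine(
    table: TripletTable,
    keywords: Iterable[str] | None = None,
    decisions: Sequence[ValidationDecision] | None = None,
) -> list[TripletTable]:
    """Run the full cascade: keyword -> complete -> dedup [-> validation].

    Returns every stage's table (input first) so callers can log the
    shrinking counts of the cascade.
    """
    stages = [table]
    if keywords is not None:
        stages.append(filter_by_keywords(stages[-1], keywords))
    stages.append(filter_complete(stages[-1]))
    stages.append(deduplicate(stages[-1]))
    if decisions:
        stages.append(apply_validation(stages[-1], decisions))
    for s in stages:
        logger.info("refinement stage %-16s: %d rows", s.stage_label, s.row_count)
    return stages


__all__ = [
    "ValidationDecision",
    "filter_by_keywords",
    "filter_complete",
    "deduplicate",
    "apply_validation",
    "refine",
]
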