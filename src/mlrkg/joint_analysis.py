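"""Joint-entity analysis: subject/object degrees and key(a,b) constraints.

An entity that recurs as subject and/or object across several distinct
triplets is a *joint* — it has multiple inputs and outputs, which is the
working definition of importance for the joint-version graph.  A constraint
``key(a, b)`` selects entities occurring as subject in ``a`` triplets and
as object in ``b``; for a level ``n`` there are exactly ``2n + 1``
constraints with ``max(a, b) = n``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._types import TripletTable
from .refinement import deduplicate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntityDegree:
    """Per-entity counts over distinct triplets."""

    entity: str
    subject_count: int
    object_count: int

    @property
    def overlap(self) -> int:
        return self.subject_count + self.object_count


@dataclass(frozen=True)
class JointConstraint:
    """key(a, b): required subject and object occurrence counts."""

    subj_required: int
    obj_required: int

    def __post_init__(self) -> None:
        if self.subj_required < 0 or self.obj_required < 0:
            raise ValueError("constraint counts must be >= 0")
        if self.subj_required == 0 and self.obj_required == 0:
            raise ValueError("key(0, 0) is not a valid constraint")


def entity_degrees(table: TripletTable) -> list[EntityDegree]:
    """Tally subject/object appearances per distinct normalised entity.

    Degrees are defined over *distinct* triplets; a non-deduplicated table
    is deduplicated internally with a warning.  Results are sorted by
    entity label for determinism.
    """
    if len(set(table.keys())) != table.row_count:
        logger.warning(
            "entity_degrees called on a non-deduplicated table "
            "(%d rows, %d distinct keys); deduplicating internally",
            table.row_count, len(set(table.keys())),
        )
        table = deduplicate(table)

    subj: dict[str, int] = {}
    obj: dict[str, int] = {}
    for t in table:
        if not t.subject.is_empty:
            subj[t.subject.normalized] = subj.get(t.subject.normalized, 0) + 1
        if not t.object.is_empty:
            obj[t.object.normalized] = obj.get(t.object.normalized, 0) + 1
    entities = sorted(set(subj) | set(obj))
    return [
        EntityDegree(e, subj.get(e, 0), obj.get(e, 0)) for e in entities
    ]


def overlap_classes(degrees: Iterable[EntityDegree]) -> dict[str, str]:
    """Colour class per entity: overlap 2 -> joint2, overlap >= 3 -> joint3.

    Overlaps above three keep the strongest class (monotone severity).
    """
    out: dict[str, str] = {}
    for d in degrees:
        if d.overlap == 2:
            out[d.entity] = "joint2"
        elif d.overlap >= 3:
            out[d.entity] = "joint3"
        else:
            out[d.entity] = "default"
    return out


def enumerate_constraints(n: int) -> list[JointConstraint]:
    """All key(a, b) constraints at level n, subject-major order.

    key(n, 0..n) then key(0..n-1, n): 2n + 1 constraints, each with
    ``max(a, b) = n``.
    """
    if n < 1:
        raise ValueError(f"constraint level must be >= 1, got {n}")
    subject_major = [JointConstraint(n, b) for b in range(n + 1)]
    object_major = [JointConstraint(a, n) for a in range(n)]
    return subject_major + object_major


def find_joints(
    degrees: Iterable[EntityDegree],
    constraint: JointConstraint,
    at_least: bool = False,
) -> list[str]:
    """Entities satisfying a key(a, b) constraint, sorted lexicographically.

    Default is exact-count matching; ``at_least=True`` switches to
    ``subject_count >= a and object_count >= b``.
    """
    if at_least:
        hits = [
            d.entity
            for d in degrees
            if d.subject_count >= constraint.subj_required
            and d.object_count >= constraint.obj_required
        ]
    else:
        hits = [
            d.entity
            for d in degrees
            if d.subject_count == constraint.subj_required
            and d.object_count == constraint.obj_required
        ]
    return sorted(hits)


__all__ = [
    "EntityDegree",
    "JointConstraint",
    "entity_degrees",
    "overlap_classes",
    "enumerate_constraints",
    "find_joints",
]
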