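"""Shared domain types for the knowledge-graph pipeline.

Everything downstream flows through these records: tagged sentences in,
(subject, relation, object) triplets out, collected into :class:`TripletTable`
instances that the refinement stages transform.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

#: Coarse part-of-speech labels. Backend-specific tagsets are collapsed to
#: this closed set so extraction rules stay backend-independent.
POS_LABELS = frozenset(
    {"noun", "verb", "adjective", "adposition", "determiner", "other"}
)

#: Closed dependency-label set. "subject"/"passive-subject" mark triplet
#: subjects, "direct-object"/"attribute"/"prepositional-object" mark objects,
#: "compound"/"modifier" attach to entity heads, "particle" extends verbs.
DEP_LABELS = frozenset(
    {
        "subject",
        "passive-subject",
        "direct-object",
        "prepositional-object",
        "attribute",
        "compound",
        "modifier",
        "particle",
        "root",
        "other",
    }
)

_PUNCT_STRIP = " \t\n\r.,;:!?\"'()[]{}"


def normalize(text: str) -> str:
    """Normalise an entity or relation label for keying.

    Lower-case, collapse internal whitespace to single spaces, strip
    leading/trailing punctuation.  This is the minimal reproducible key
    used for deduplication, node identity and keyword matching.
    """
    collapsed = re.sub(r"\s+", " ", text.strip())
    return collapsed.strip(_PUNCT_STRIP).lower()


@dataclass(frozen=True)
class Document:
    """A plain-text article, line endings normalised to ``\\n``."""

    doc_id: str
    body: str
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class TaggedToken:
    """One token of a tagged sentence.

    ``head`` is the in-sentence index of the governing token; the root
    token has ``dep == "root"`` and is its own head.
    """

    index: int
    surface: str
    lemma: str
    pos: str
    dep: str
    head: int

    def __post_init__(self) -> None:
        if self.pos not in POS_LABELS:
            raise ValueError(f"unknown pos label {self.pos!r}")
        if self.dep not in DEP_LABELS:
            raise ValueError(f"unknown dep label {self.dep!r}")


@dataclass(frozen=True)
class Sentence:
    doc_id: str
    sent_index: int
    tokens: tuple[TaggedToken, ...]
    raw: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        self.validate()

    def validate(self) -> None:
        """Enforce the tagged-sentence invariants.

        Token indices must be contiguous from 0, head indices in bounds,
        and exactly one root token that is its own head.
        """
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise ValueError(
                    f"token indices not contiguous at position {i} "
                    f"(doc {self.doc_id!r}, sentence {self.sent_index})"
                )
            if not 0 <= tok.head < n:
                raise ValueError(
                    f"head index {tok.head} out of bounds for token {i}"
                )
        roots = [t for t in self.tokens if t.dep == "root"]
        if n and len(roots) != 1:
            raise ValueError(
                f"sentence must have exactly one root, found {len(roots)}"
            )
        if roots and roots[0].head != roots[0].index:
            raise ValueError("root token must be its own head")


@dataclass(frozen=True)
class EntityPhrase:
    """A multi-word entity: a head token plus its compound/modifier members.

    ``surface`` joins member tokens in sentence order with single spaces;
    ``normalized`` is the keying form.
    """

    head_index: int
    member_indices: tuple[int, ...]
    surface: str
    normalized: str

    @classmethod
    def empty(cls) -> "EntityPhrase":
        return cls(head_index=-1, member_indices=(), surface="", normalized="")

    @property
    def is_empty(self) -> bool:
        return not self.member_indices

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "member_indices", tuple(self.member_indices)
        )
        if self.member_indices:
            if self.head_index not in self.member_indices:
                raise ValueError("head_index must be a member index")
            if not self.surface:
                raise ValueError("non-empty phrase needs a surface form")


@dataclass(frozen=True)
class Triplet:
    """One (subject, relation, object) record with sentence provenance.

    ``complete`` is True iff all three slots are non-empty; it is derived,
    never stored independently.
    """

    subject: EntityPhrase
    relation: str
    object: EntityPhrase
    doc_id: str = ""
    sent_index: int = -1

    @property
    def complete(self) -> bool:
        return (
            not self.subject.is_empty
            and bool(self.relation)
            and not self.object.is_empty
        )

    @property
    def key(self) -> tuple[str, str, str]:
        """Normalised (source, edge, target) deduplication key."""
        return (
            self.subject.normalized,
            normalize(self.relation),
            self.object.normalized,
        )

    @classmethod
    def from_strings(
        cls,
        subject: str,
        relation: str,
        obj: str,
        doc_id: str = "",
        sent_index: int = -1,
    ) -> "Triplet":
        """Build a triplet from bare strings (e.g. a CSV row)."""

        def phrase(text: str) -> EntityPhrase:
            if not text:
                return EntityPhrase.empty()
            return EntityPhrase(
                head_index=0,
                member_indices=(0,),
                surface=text,
                normalized=normalize(text),
            )

        return cls(phrase(subject), relation, phrase(obj), doc_id, sent_index)


@dataclass
class TripletTable:
    """Ordered collection of triplets; the unit flowing through refinement."""

    rows: list[Triplet] = field(default_factory=list)
    stage_label: str = "raw"

    @property
    def row_count(self) -> int:
        return len(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[Triplet]:
        return iter(self.rows)

    def __getitem__(self, i: int) -> Triplet:
        return self.rows[i]

    def with_rows(self, rows: Iterable[Triplet], stage_label: str) -> "TripletTable":
        return TripletTable(rows=list(rows), stage_label=stage_label)

    def keys(self) -> list[tuple[str, str, str]]:
        return [t.key for t in self.rows]

    def copy(self) -> "TripletTable":
        return TripletTable(rows=list(self.rows), stage_label=self.stage_label)


__all__ = [
    "POS_LABELS",
    "DEP_LABELS",
    "normalize",
    "Document",
    "TaggedToken",
    "Sentence",
    "EntityPhrase",
    "Triplet",
    "TripletTable",
]
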