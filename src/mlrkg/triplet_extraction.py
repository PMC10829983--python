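"""Dependency-based SVO triplet extraction.

Each tagged sentence is disassembled into zero or more (subject, relation,
object) candidates: one triplet per verb token, with multi-word entity
phrases assembled from compound/modifier dependents.  A triplet is emitted
even when a slot is empty (``complete=False``); downstream refinement
decides what survives.

Extraction is deterministic and its oracle is exact: on synthetic corpora
with planted SVO structure the extracted set must equal the planted set.
"""
from __future__ import annotations

from typing import Iterable, Sequence

from ._types import EntityPhrase, Sentence, TaggedToken, Triplet, TripletTable, normalize

_SUBJECT_DEPS = frozenset({"subject", "passive-subject"})
_DIRECT_OBJECT_DEPS = frozenset({"direct-object", "attribute"})
_PHRASE_MEMBER_DEPS = frozenset({"compound", "modifier"})


def extract_entity_phrase(sentence: Sentence, head_index: int) -> EntityPhrase:
    """Assemble the entity phrase rooted at ``head_index``.

    Members are the head plus every token whose dep is compound/modifier and
    whose head chain reaches the head without crossing a verb.  The surface
    preserves sentence order.
    """
    tokens = sentence.tokens
    if not 0 <= head_index < len(tokens):
        raise IndexError(
            f"head_index {head_index} out of range for sentence of "
            f"{len(tokens)} tokens"
        )

    members = {head_index}
    for tok in tokens:
        if tok.index == head_index or tok.dep not in _PHRASE_MEMBER_DEPS:
            continue
        if _chain_reaches(tokens, tok.index, head_index):
            members.add(tok.index)

    ordered = tuple(sorted(members))
    surface = " ".join(tokens[i].surface for i in ordered)
    return EntityPhrase(
        head_index=head_index,
        member_indices=ordered,
        surface=surface,
        normalized=normalize(surface),
    )


def _chain_reaches(
    tokens: Sequence[TaggedToken], start: int, target: int
) -> bool:
    """Follow head links from ``start``; True if ``target`` is reached
    before a verb, a cycle, or a self-loop."""
    seen = set()
    i = start
    while i not in seen:
        seen.add(i)
        nxt = tokens[i].head
        if nxt == target:
            return True
        if nxt == i or tokens[nxt].pos == "verb":
            return False
        i = nxt
    return False


def extract_triplets(
    sentence: Sentence, *, lemma_relations: bool = False
) -> list[Triplet]:
    """Extract one candidate triplet per verb token.

    For each verb V: the subject is the phrase of the first token with a
    subject dependency headed by V; the object is the phrase of the first
    direct object or attribute headed by V, else the first prepositional
    object reachable through one adposition headed by V.  For prepositional
    objects the relation is the verb surface plus the adposition ("binds
    to").  ``lemma_relations`` switches relations to lemma form.
    """
    tokens = sentence.tokens
    triplets: list[Triplet] = []

    for verb in tokens:
        if verb.pos != "verb":
            continue

        subject = EntityPhrase.empty()
        for tok in tokens:
            if tok.dep in _SUBJECT_DEPS and tok.head == verb.index:
                subject = extract_entity_phrase(sentence, tok.index)
                break

        obj = EntityPhrase.empty()
        adposition: TaggedToken | None = None
        for tok in tokens:
            if tok.dep in _DIRECT_OBJECT_DEPS and tok.head == verb.index:
                obj = extract_entity_phrase(sentence, tok.index)
                break
        if obj.is_empty:
            # one-adposition hop: V -> adposition -> prepositional object
            adp_indices = {
                t.index
                for t in tokens
                if t.pos == "adposition" and t.head == verb.index
            }
            for tok in tokens:
                if (
                    tok.dep == "prepositional-object"
                    and tok.head in adp_indices
                ):
                    obj = extract_entity_phrase(sentence, tok.index)
                    adposition = tokens[tok.head]
                    break

        relation = verb.lemma if lemma_relations else verb.surface
        particles = [
            t.surface for t in tokens
            if t.dep == "particle" and t.head == verb.index
        ]
        if particles:
            relation = " ".join([relation, *particles])
        if adposition is not None:
            relation = f"{relation} {adposition.surface}"

        triplets.append(
            Triplet(
                subject=subject,
                relation=relation,
                object=obj,
                doc_id=sentence.doc_id,
                sent_index=sentence.sent_index,
            )
        )
    return triplets


def extract_corpus(
    sentences: Iterable[Sentence], *, lemma_relations: bool = False
) -> TripletTable:
    """Run extraction over a corpus; rows keep document order and provenance."""
    rows: list[Triplet] = []
    for sent in sentences:
        rows.extend(extract_triplets(sent, lemma_relations=lemma_relations))
    return TripletTable(rows=rows, stage_label="extracted")


__all__ = ["extract_entity_phrase", "extract_triplets", "extract_corpus"]
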