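"""Article ingestion: loading text, sentence segmentation, tagged-token I/O.

The tagger is a *contract*, not a dependency: any callable backend that maps
text to sentences of :class:`TaggedToken` qualifies.  The shipped
:class:`RuleTagger` is a deterministic lexicon-driven backend that covers
the closed dependency set; production users can plug a full statistical
parser behind the same protocol without touching the extraction rules.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from ._types import DEP_LABELS, POS_LABELS, Document, Sentence, TaggedToken
from .errors import EncodingError, InputError, ParseError

# ---------------------------------------------------------------------------
# Document loading


def load_document(path: str | Path, doc_id: str | None = None) -> Document:
    """Read a UTF-8 text file into a :class:`Document`.

    Line endings are normalised to ``\\n``.  A missing file raises
    :class:`InputError`; undecodable bytes raise :class:`EncodingError`
    naming the byte offset.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except FileNotFoundError as exc:
        raise InputError(f"input file not found: {path}") from exc
    except OSError as exc:
        raise InputError(f"cannot read input file {path}: {exc}") from exc
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise EncodingError(
            f"{path} is not valid UTF-8 at byte offset {exc.start}"
        ) from exc
    body = text.replace("\r\n", "\n").replace("\r", "\n")
    return Document(doc_id=doc_id or path.stem, body=body, source_path=str(path))


# ---------------------------------------------------------------------------
# Tagger contract


class Tagger(Protocol):
    """Any backend mapping raw text to tagged sentences.

    Returns a list of ``(raw_sentence, tokens)`` pairs in document order;
    every token list must satisfy the :class:`Sentence` invariants.
    """

    def tag(self, text: str) -> list[tuple[str, list[TaggedToken]]]:
        ...


def segment_sentences(doc: Document, tagger: Tagger) -> list[Sentence]:
    """Segment a document into tagged sentences via the tagger contract."""
    try:
        tagged = tagger.tag(doc.body)
    except Exception as exc:  # contract: propagate with provenance
        raise InputError(
            f"tagger failed on document {doc.doc_id!r} "
            f"(body of {len(doc.body)} characters): {exc}"
        ) from exc
    return [
        Sentence(doc_id=doc.doc_id, sent_index=i, tokens=tuple(tokens), raw=raw)
        for i, (raw, tokens) in enumerate(tagged)
    ]


# ---------------------------------------------------------------------------
# Rule-based tagger

#: Verbs the rule tagger recognises.  The synthetic corpus generator draws
#: its predicates from this same lexicon, which is what makes generation and
#: re-tagging mutually consistent.
VERB_LEXICON = frozenset(
    {
        "is",
        "am",
        "are",
        "was",
        "were",
        "treats",
        "causes",
        "reduces",
        "induces",
        "includes",
        "included",
        "include",
        "recommends",
        "recommended",
        "improves",
        "improve",
        "binds",
        "relieves",
        "relieved",
        "monitored",
        "suggests",
        "requires",
        "prevents",
        "triggers",
        "worsens",
        "controls",
        "delivered",
        "add",
        "appear",
        "respond",
        "may",
        "used",
        "signaling",
        "persists",
        "associated",
    }
)

ADPOSITION_LEXICON = frozenset({"to", "with", "of", "in", "by", "for"})

_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")


class RuleTagger:
    """Deterministic lexicon-driven tagger for the closed dependency set.

    Sentence segmentation splits on ``.``, ``!`` or ``?`` followed by
    whitespace.  Within a sentence the first lexicon verb becomes the root;
    tokens before it form the subject phrase (last token is the head), and
    tokens after it form the object phrase, optionally attached through a
    single adposition ("binds **to** cell eosinophils").
    """

    def __init__(
        self,
        verbs: frozenset[str] = VERB_LEXICON,
        adpositions: frozenset[str] = ADPOSITION_LEXICON,
    ) -> None:
        self.verbs = verbs
        self.adpositions = adpositions

    def tag(self, text: str) -> list[tuple[str, list[TaggedToken]]]:
        out: list[tuple[str, list[TaggedToken]]] = []
        for chunk in _SENT_SPLIT.split(text):
            raw = chunk.strip()
            if not raw:
                continue
            out.append((raw, self._tag_sentence(raw)))
        return out

    def _tag_sentence(self, raw: str) -> list[TaggedToken]:
        words = raw.split()
        if words:
            words[-1] = words[-1].rstrip(".!?")
            if not words[-1]:
                words.pop()
        if not words:
            return []

        lowers = [w.lower() for w in words]
        n = len(words)
        verb_ix = next(
            (i for i, w in enumerate(lowers) if w in self.verbs), None
        )

        pos = ["noun"] * n
        dep = ["other"] * n
        head = list(range(n))

        if verb_ix is None:
            # No predicate: everything hangs off a nominal root.
            dep[-1] = "root"
            for i in range(n - 1):
                dep[i] = "other"
                head[i] = n - 1
            return self._build(words, lowers, pos, dep, head)

        pos[verb_ix] = "verb"
        dep[verb_ix] = "root"
        head[verb_ix] = verb_ix

        # A trailing lexicon verb directly after the root extends the
        # predicate ("may respond"); keep it simple: only the root is a verb.

        if verb_ix > 0:
            subj_head = verb_ix - 1
            dep[subj_head] = "subject"
            head[subj_head] = verb_ix
            for i in range(subj_head):
                dep[i] = "compound"
                head[i] = subj_head

        rest = list(range(verb_ix + 1, n))
        if rest:
            first = rest[0]
            if lowers[first] in self.adpositions:
                pos[first] = "adposition"
                dep[first] = "other"
                head[first] = verb_ix
                obj_tokens = rest[1:]
                obj_dep = "prepositional-object"
                obj_attach = first
            else:
                obj_tokens = rest
                obj_dep = "direct-object"
                obj_attach = verb_ix
            if obj_tokens:
                obj_head = obj_tokens[-1]
                dep[obj_head] = obj_dep
                head[obj_head] = obj_attach
                for i in obj_tokens[:-1]:
                    dep[i] = "compound"
                    head[i] = obj_head

        return self._build(words, lowers, pos, dep, head)

    @staticmethod
    def _build(
        words: list[str],
        lowers: list[str],
        pos: list[str],
        dep: list[str],
        head: list[int],
    ) -> list[TaggedToken]:
        return [
            TaggedToken(
                index=i,
                surface=words[i],
                lemma=lowers[i],
                pos=pos[i],
                dep=dep[i],
                head=head[i],
            )
            for i in range(len(words))
        ]


# ---------------------------------------------------------------------------
# Tagged-record serialisation (JSON Lines, one token per line)

_TOKEN_FIELDS = ("index", "surface", "lemma", "pos", "dep", "head")


def write_tagged_records(sentences: Sequence[Sentence], path: str | Path) -> None:
    """Serialise sentences as JSON Lines, one token object per line.

    The first token of each sentence carries ``"sent_break": true`` plus the
    sentence provenance (``doc_id``, ``sent_index``, ``raw``).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in sentences:
            for j, tok in enumerate(sent.tokens):
                rec: dict = {f: getattr(tok, f) for f in _TOKEN_FIELDS}
                if j == 0:
                    rec["sent_break"] = True
                    rec["doc_id"] = sent.doc_id
                    rec["sent_index"] = sent.sent_index
                    rec["raw"] = sent.raw
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_tagged_records(path: str | Path) -> list[Sentence]:
    """Parse a tagged-record JSONL file back into sentences.

    Round-trips with :func:`write_tagged_records`.  A malformed record
    raises :class:`ParseError` with its line number.
    """
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except FileNotFoundError as exc:
        raise InputError(f"tagged-record file not found: {path}") from exc

    sentences: list[Sentence] = []
    current: list[TaggedToken] = []
    meta: dict = {}

    def flush() -> None:
        if current:
            sent_index = meta.get("sent_index")
            if sent_index is None:
                sent_index = len(sentences)
            sentences.append(
                Sentence(
                    doc_id=meta.get("doc_id", ""),
                    sent_index=sent_index,
                    tokens=tuple(current),
                    raw=meta.get("raw", ""),
                )
            )

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            if rec.get("sent_break"):
                flush()
                current = []
                meta = {
                    "doc_id": rec.get("doc_id", ""),
                    "sent_index": rec.get("sent_index"),
                    "raw": rec.get("raw", ""),
                }
            tok = TaggedToken(**{f: rec[f] for f in _TOKEN_FIELDS})
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: malformed tagged record at line {lineno}: {exc}"
            ) from exc
        current.append(tok)
    flush()
    return sentences


__all__ = [
    "load_document",
    "segment_sentences",
    "Tagger",
    "RuleTagger",
    "VERB_LEXICON",
    "ADPOSITION_LEXICON",
    "write_tagged_records",
    "read_tagged_records",
]
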