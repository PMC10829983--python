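"""Seed-reproducible synthetic corpora with planted ground truth.

Every other module's oracle lives here: the generator emits pre-tagged
sentences whose SVO structure, incomplete-triplet fraction, duplicate
fraction, per-entity degrees and pair frequencies are *planted* and
recorded in a :class:`FixtureManifest`.  Extraction, refinement, joint
analysis and prediction are then tested against the manifest exactly — no
statistical tolerance, no model downloads.

Generation is a pure function of the config (seed included), and manifest
/corpus consistency is itself checked at generation time by re-tagging the
raw sentences and re-extracting the planted triplets.
"""
from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from ._types import Sentence, Triplet, TripletTable, normalize
from .corpus_ingest import ADPOSITION_LEXICON, VERB_LEXICON, RuleTagger
from .errors import ConfigurationError
from .ranking_eval import RankedTriplet
from .triplet_extraction import extract_corpus


def _load_vocabulary() -> dict:
    with resources.files("mlrkg.data").joinpath("vocabulary.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


_VOCAB = _load_vocabulary()


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic corpus.

    ``p_incomplete`` and ``p_duplicate`` are fractions of the generic
    sentence budget (what remains after joint- and pair-planting sentences
    are allocated); ``keyword_fraction`` is the fraction of generic
    *complete* sentences that carry ``keyword`` in their subject phrase.
    """

    n_sentences: int
    p_incomplete: float = 0.15
    p_duplicate: float = 0.10
    planted_joints: tuple[tuple[str, int, int], ...] = ()
    pair_frequency_profile: tuple[tuple[tuple[str, str], int], ...] = ()
    keyword_fraction: float = 0.4
    keyword: str = "asthma"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_incomplete", "p_duplicate", "keyword_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_sentences < 0:
            raise ConfigurationError("n_sentences must be >= 0")
        object.__setattr__(
            self, "planted_joints", tuple(tuple(j) for j in self.planted_joints)
        )
        object.__setattr__(
            self,
            "pair_frequency_profile",
            tuple((tuple(p), c) for p, c in self.pair_frequency_profile),
        )


@dataclass
class FixtureManifest:
    """The oracle record: exactly what was planted, per sentence."""

    planted_keys: list[tuple[str, str, str]]  # one per sentence, "" slots allowed
    complete_flags: list[bool]
    degrees: dict[str, tuple[int, int]]  # on the deduplicated complete table
    pair_frequencies: dict[tuple[str, str], int]  # unordered, complete rows
    duplicate_keys: list[tuple[str, str, str]]
    n_keyword_rows: int
    keyword: str

    @property
    def n_sentences(self) -> int:
        return len(self.planted_keys)

    @property
    def n_complete(self) -> int:
        return sum(self.complete_flags)

    @property
    def n_incomplete(self) -> int:
        return self.n_sentences - self.n_complete

    @property
    def complete_key_multiset(self) -> Counter:
        return Counter(
            k for k, c in zip(self.planted_keys, self.complete_flags) if c
        )

    @property
    def n_distinct_complete_keys(self) -> int:
        return len(self.complete_key_multiset)


# ---------------------------------------------------------------------------
# Sentence planning


def _check_entity_words(label: str, what: str) -> list[str]:
    words = normalize(label).split()
    if not words:
        raise ConfigurationError(f"{what} label {label!r} is empty")
    for w in words:
        if w in VERB_LEXICON or w in ADPOSITION_LEXICON:
            raise ConfigurationError(
                f"{what} label {label!r} contains lexicon word {w!r}; "
                "entity labels must not collide with verbs or adpositions"
            )
    return words


def _entity_phrase_words(rng: random.Random, keyword: str | None = None) -> list[str]:
    """1-3 token noun phrase from the themed vocabulary."""
    words: list[str] = []
    n_mods = rng.choice((0, 0, 1, 1, 2))
    words.extend(rng.sample(_VOCAB["modifiers"], n_mods))
    if keyword:
        words.append(keyword)
    else:
        words.append(rng.choice(_VOCAB["nouns"]))
    return words


def _pick_predicate(rng: random.Random) -> tuple[str, str | None]:
    if rng.random() < 0.2:
        verb, adp = rng.choice(_VOCAB["prepositional_verbs"])
        return verb, adp
    return rng.choice(_VOCAB["verbs"]), None


@dataclass
class _Plan:
    subj: list[str]
    verb: str | None
    adp: str | None
    obj: list[str]

    def words(self) -> list[str]:
        out = list(self.subj)
        if self.verb:
            out.append(self.verb)
        if self.adp:
            out.append(self.adp)
        out.extend(self.obj)
        return out

    def key(self) -> tuple[str, str, str]:
        rel = self.verb or ""
        if self.adp:
            rel = f"{rel} {self.adp}"
        return (" ".join(self.subj), normalize(rel), " ".join(self.obj))

    @property
    def complete(self) -> bool:
        return bool(self.subj) and bool(self.verb) and bool(self.obj)


def generate(
    config: FixtureConfig, doc_id: str = "fixture"
) -> tuple[list[Sentence], TripletTable, FixtureManifest]:
    """Generate (corpus, extracted table, manifest) for one config.

    Sentence budget: joint-planting sentences first (one per required
    subject/object occurrence), then pair-profile sentences, then generic
    sentences carrying the incomplete/duplicate/keyword fractions.  An
    infeasible budget raises :class:`ConfigurationError`.
    """
    rng = random.Random(config.seed)
    plans: list[_Plan] = []

    # --- joint-planting sentences: entity at exact (subject, object) degree
    partner_serial = 0
    joint_words: set[str] = set()
    for entity, subj_count, obj_count in config.planted_joints:
        words = _check_entity_words(entity, "planted joint")
        joint_words.update(words)
        if subj_count < 0 or obj_count < 0:
            raise ConfigurationError(
                f"planted joint {entity!r} has negative counts"
            )
        for _ in range(subj_count):
            partner = [f"partner{partner_serial:04d}"]
            partner_serial += 1
            verb, adp = _pick_predicate(rng)
            plans.append(_Plan(words, verb, adp, partner))
        for _ in range(obj_count):
            partner = [f"partner{partner_serial:04d}"]
            partner_serial += 1
            verb, adp = _pick_predicate(rng)
            plans.append(_Plan(partner, verb, adp, words))

    # --- pair-frequency sentences
    for (a, b), count in config.pair_frequency_profile:
        wa = _check_entity_words(a, "pair entity")
        wb = _check_entity_words(b, "pair entity")
        if count < 0:
            raise ConfigurationError(f"pair ({a!r}, {b!r}) has negative count")
        for _ in range(count):
            verb, adp = _pick_predicate(rng)
            plans.append(_Plan(wa, verb, adp, wb))

    n_reserved = len(plans)
    n_generic = config.n_sentences - n_reserved
    if n_generic < 0:
        raise ConfigurationError(
            f"planted joints and pair profile need {n_reserved} sentences "
            f"but n_sentences is only {config.n_sentences}"
        )

    n_incomplete = round(config.p_incomplete * n_generic)
    n_duplicate = round(config.p_duplicate * n_generic)
    n_complete_generic = n_generic - n_incomplete - n_duplicate
    if n_complete_generic < 0:
        raise ConfigurationError(
            "p_incomplete and p_duplicate together exceed the generic budget"
        )
    if n_duplicate > 0 and n_complete_generic == 0:
        raise ConfigurationError(
            "duplicates requested but no complete generic sentence to repeat"
        )
    n_keyword = round(config.keyword_fraction * n_complete_generic)
    keyword = normalize(config.keyword)
    if keyword and (keyword in VERB_LEXICON or keyword in ADPOSITION_LEXICON):
        raise ConfigurationError(f"keyword {keyword!r} collides with the lexicon")

    # --- generic complete sentences, unique keys, keyword planted first
    generic_plans: list[_Plan] = []
    used_keys = {p.key() for p in plans}
    for i in range(n_complete_generic):
        for _attempt in range(200):
            subj = _entity_phrase_words(rng, keyword if i < n_keyword else None)
            verb, adp = _pick_predicate(rng)
            obj = _entity_phrase_words(rng)
            plan = _Plan(subj, verb, adp, obj)
            key = plan.key()
            if key not in used_keys and not (
                joint_words & set(subj) or joint_words & set(obj)
            ):
                used_keys.add(key)
                generic_plans.append(plan)
                break
        else:  # pragma: no cover - vocabulary is large enough in practice
            raise ConfigurationError(
                "could not plant a unique generic triplet; "
                "n_sentences too large for the vocabulary"
            )
    plans.extend(generic_plans)

    # --- incomplete sentences: missing subject or missing object
    for _ in range(n_incomplete):
        if rng.random() < 0.5:
            verb, adp = _pick_predicate(rng)
            plans.append(_Plan([], verb, adp, _entity_phrase_words(rng)))
        else:
            verb = rng.choice(_VOCAB["intransitive_verbs"])
            plans.append(_Plan(_entity_phrase_words(rng), verb, None, []))

    # --- duplicates: verbatim repeats of earlier generic complete sentences
    duplicate_keys: list[tuple[str, str, str]] = []
    for _ in range(n_duplicate):
        base = rng.choice(generic_plans)
        plans.append(_Plan(base.subj, base.verb, base.adp, base.obj))
        duplicate_keys.append(base.key())

    rng.shuffle(plans)

    # --- realise sentences through the tagger itself, guaranteeing that
    #     re-tagging the raw text reproduces the planted structure
    tagger = RuleTagger()
    corpus: list[Sentence] = []
    for i, plan in enumerate(plans):
        raw = " ".join(plan.words()) + "."
        tagged = tagger.tag(raw)
        assert len(tagged) == 1, f"planted sentence split unexpectedly: {raw!r}"
        corpus.append(
            Sentence(doc_id=doc_id, sent_index=i, tokens=tuple(tagged[0][1]),
                     raw=tagged[0][0])
        )

    table = extract_corpus(corpus)

    # --- manifest, from the plan (the oracle side)
    planted_keys = [p.key() for p in plans]
    complete_flags = [p.complete for p in plans]

    complete_plans = [p for p in plans if p.complete]
    distinct: dict[tuple[str, str, str], _Plan] = {}
    for p in complete_plans:
        distinct.setdefault(p.key(), p)
    subj_deg: Counter = Counter()
    obj_deg: Counter = Counter()
    for p in distinct.values():
        subj_deg[" ".join(p.subj)] += 1
        obj_deg[" ".join(p.obj)] += 1
    degrees = {
        e: (subj_deg.get(e, 0), obj_deg.get(e, 0))
        for e in sorted(set(subj_deg) | set(obj_deg))
    }

    pair_freq: Counter = Counter()
    for p in complete_plans:
        s, o = " ".join(p.subj), " ".join(p.obj)
        pair_freq[(s, o) if s <= o else (o, s)] += 1

    n_keyword_rows = 0
    if keyword:
        n_keyword_rows = sum(
            1
            for p in plans
            if any(keyword in w for w in p.subj)
            or any(keyword in w for w in p.obj)
        )

    manifest = FixtureManifest(
        planted_keys=planted_keys,
        complete_flags=complete_flags,
        degrees=degrees,
        pair_frequencies=dict(pair_freq),
        duplicate_keys=duplicate_keys,
        n_keyword_rows=n_keyword_rows,
        keyword=keyword,
    )

    _check_consistency(table, manifest)
    return corpus, table, manifest


def _check_consistency(table: TripletTable, manifest: FixtureManifest) -> None:
    """Generation-time invariant: extraction recovers the plan exactly."""
    extracted = [t.key for t in table]
    if extracted != manifest.planted_keys:
        raise AssertionError(
            "fixture generation inconsistency: extracted keys differ from "
            "planted keys"
        )
    flags = [t.complete for t in table]
    if flags != manifest.complete_flags:
        raise AssertionError(
            "fixture generation inconsistency: completeness flags differ"
        )


# ---------------------------------------------------------------------------
# Purpose-built small fixtures


def replicated_table(
    n_rows: int = 860, n_distinct: int = 202, seed: int = 0
) -> TripletTable:
    """A table of ``n_rows`` built by repeating ``n_distinct`` base keys.

    Mirrors the overlap-elimination stage of a refinement cascade:
    deduplication must return exactly ``n_distinct`` rows.
    """
    if n_distinct < 1 or n_rows < n_distinct:
        raise ConfigurationError("need n_rows >= n_distinct >= 1")
    rng = random.Random(seed)
    base = [
        Triplet.from_strings(f"entity{i:04d}", "relates", f"entity{i + 1:04d}")
        for i in range(n_distinct)
    ]
    rows = list(base)
    while len(rows) < n_rows:
        rows.append(rng.choice(base))
    rng.shuffle(rows)
    return TripletTable(rows=rows, stage_label="replicated")


#: Comorbidity neighbours planted around the query keyword in
#: :func:`comorbidity_table`.
COMORBIDITIES = ("allergies", "obesity", "depression", "copd", "gerd", "rhinitis")


def comorbidity_table(keyword: str = "asthma") -> TripletTable:
    """A small comorbidity-style table: keyword <-> six conditions.

    Edges run in both directions plus unrelated background rows, so a
    depth-1 distillation for the keyword must surface all six neighbours.
    """
    rows = []
    for i, cond in enumerate(COMORBIDITIES):
        if i % 2 == 0:
            rows.append(Triplet.from_strings(keyword, "associated with", cond))
        else:
            rows.append(Triplet.from_strings(cond, "worsens", keyword))
    rows.append(Triplet.from_strings("obesity", "causes", "apnea"))
    rows.append(Triplet.from_strings("rhinitis", "includes", "sinusitis"))
    rows.append(Triplet.from_strings("dermatitis", "suggests", "allergies"))
    return TripletTable(rows=rows, stage_label="comorbidity-fixture")


def paper_scenario() -> tuple[list[RankedTriplet], TripletTable]:
    """The worked chatbot-evaluation scenario.

    A deterministic deduplicated ground truth of 202 distinct triplets and
    a 10-item ranked prediction list whose rank-1 and rank-3 items —
    (Asthma, Am, Asthma) and (Exacerbation, Am, Asthma) — occur in the
    truth while the other eight do not.  The rank-1 hit carries relevance
    grade 1 and the rank-3 hit grade 2.
    """
    truth_rows = [
        Triplet.from_strings("Asthma", "Am", "Asthma"),
        Triplet.from_strings("Exacerbation", "Am", "Asthma"),
    ]
    for i in range(200):
        truth_rows.append(
            Triplet.from_strings(f"finding{i:03d}", "indicates", f"condition{i:03d}")
        )
    truth = TripletTable(rows=truth_rows, stage_label="ground-truth")

    hit_keys = {1: ("asthma", "am", "asthma"),
                3: ("exacerbation", "am", "asthma")}
    grades = {1: 1, 3: 2}
    predicted = []
    for rank in range(1, 11):
        if rank in hit_keys:
            key = hit_keys[rank]
            rel = grades[rank]
        else:
            key = (f"query{rank}", "am", "asthma")
            rel = 0
        predicted.append(RankedTriplet(key=key, rank=rank, relevance=rel))
    return predicted, truth


__all__ = [
    "FixtureConfig",
    "FixtureManifest",
    "generate",
    "replicated_table",
    "comorbidity_table",
    "COMORBIDITIES",
    "paper_scenario",
]
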