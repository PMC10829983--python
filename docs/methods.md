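# Methods

## Pipeline model

The package treats knowledge-graph construction as a sequence of total,
deterministic transformations on a `TripletTable`. A triplet is one
(subject, relation, object) record with sentence provenance; its
`complete` flag is always derived from the three slots, never stored.
Entity and relation identity is the *normalised* form throughout: lower
case, internal whitespace collapsed, leading/trailing punctuation
stripped. That normalisation is the deduplication key, the graph node
identity and the keyword-matching domain, so a choice made once applies
consistently everywhere downstream.

## Tagging and extraction

Tagging is a contract (`corpus_ingest.Tagger`): any backend that maps text
to sentences of tokens with a coarse part-of-speech label and a dependency
label from a closed set (subject, passive-subject, direct-object,
prepositional-object, attribute, compound, modifier, particle, root,
other) qualifies. Extraction counts are inherently tagger-dependent —
different parser versions disassemble the same corpus into different
numbers of triplets — which is why the package pins its *rules*, not a
parser. The shipped `RuleTagger` is a deterministic lexicon-driven
backend: sentences split on `.` `!` `?` followed by whitespace, the first
lexicon verb is the root, pre-verbal tokens form the subject phrase
(rightmost token as head) and post-verbal tokens the object phrase,
optionally attached through a single adposition. It exists so that the
whole pipeline, including its exact-equality oracles, runs with no model
download; it is not a general-purpose parser.

Extraction emits one triplet per verb and takes the *first* subject and
first object dependent only — no cross-product over conjuncts — keeping
output size linear in verb count. Relations are verb surface forms (a
lemma mode is a switch), suffixed with the adposition when the object is
prepositional ("binds to"); modal-only and copular predicates are allowed
as relations. Entity phrases collect compound/modifier dependents whose
head chain reaches the phrase head without crossing a verb.

## Refinement cascade

Stage order is fixed: keyword filter → completeness filter →
deduplication, with expert validation as an optional final stage. Each
stage preserves row order and is non-increasing in row count, so the
composed cascade is monotone — the property that replaces any particular
corpus's shrinking counts, which depend on the tagger and on a domain
keyword list that is user-supplied configuration. Keyword matching is
substring-per-token on normalised entities ("asthma" matches "severe
asthma" but a keyword never matches across token boundaries).
Deduplication keeps the first occurrence of each normalised key and is
idempotent. Conflicting validation verdicts for one key are an error, not
a tie-break.

## Graph model

The graph is a directed *multigraph*: repeated rows become parallel edges,
because merging them silently would blur the boundary between extraction
and deduplication. Node labels are normalised entities with original-case
surfaces kept for display. `top_relations` ranks relation labels by
descending frequency with lexicographic tie-break; `k` defaults to 10 in
the CLI and is a free parameter (descriptions of the method vary between
10 and 15). The interactive export writes one self-contained HTML file —
graph embedded once as JSON in a `kg-data` script tag, rendered by an
inline canvas script with zoom, pan and node dragging — so it opens
offline. Colour classes are fixed hues: `default` #1f78b4 (blue),
`joint2` #ff7f0e (orange), `joint3` #6a3d9a (purple), overridable per
export.

## Joint entities

Degrees are defined over *distinct complete* triplets (a non-deduplicated
table is deduplicated internally with a warning). An entity's overlap is
`subject_count + object_count`; overlap 2 maps to the orange class,
overlap 3 to purple, and overlaps above 3 stay purple (monotone severity —
the colour scale stops at three). `key(a, b)` matches *exact* counts by
default, reading "having four subject entities and three object entities"
literally; an at-least mode is a flag, and exact-mode results are always a
subset of at-least-mode results. `enumerate_constraints(n)` returns
key(n, 0..n) then key(0..n−1, n): `2n + 1` constraints, each with
`max(a, b) = n`.

## Distillation

A query keyword selects seed nodes (case-insensitive substring match by
default, exact as an option); depth 1 returns every edge touching a seed
regardless of direction, and depth *d* expands edge-induced from nodes
captured at shallower depths. Results are monotone in depth, idempotent at
equal depth, and always subgraphs of the input. Depth defaults to 1.

## Evaluation conventions

Predicted query triplets are the k most frequent unordered co-occurring
entity pairs (ties lexicographic, orientation from the first observed
row), each cast with a template relation (default "Am"). Two conventions
are deliberately nonstandard, matching the system being evaluated:

* **MRR and MAP normalise by ground-truth size**, not query count:
  MRR = (Σ 1/rank_i)/|truth|, MAP = (Σ rel_i/rank_i)/|truth|. The
  textbook per-query variants sit behind `per_query=True`.
* **DCG discount**: gain at rank 1 is undiscounted, at rank i ≥ 2 it is
  rel_i/log2(i) — note log2(2) = 1, so rank 2 is also effectively
  undiscounted. The common rel_i/log2(i+1) convention is selectable.

In `evaluate`, MAP uses a hit's stored relevance grade when positive
(falling back to 1), while DCG is binary hit/miss unless an explicit grade
map is supplied; this mirrors worked evaluations in which graded relevance
enters MAP but nDCG is computed on binary hits. Reports round half-up to
4 decimal places; internal comparisons in tests use absolute tolerance
5×10⁻⁵. With zero denominators every ratio is defined as 0.

## Synthetic corpora

`synthetic_fixtures.generate` is a pure function of its config (one seeded
`random.Random`, no global state). The sentence budget allocates
joint-planting sentences first (one per required subject/object
occurrence, each with a fresh partner entity so planted degrees are
exact), then pair-frequency sentences, then generic sentences carrying the
incomplete, duplicate and keyword fractions. Default study conditions:
15 % incomplete triplets, 10 % verbatim duplicates, 40 % of complete
generic sentences carrying the query keyword in the subject — a corpus
dirty enough that every refinement stage has work to do while staying
exactly accountable. Vocabulary is data (a themed JSON word list:
drug-like, symptom-like, comorbidity-like tokens) disjoint from the
tagger's verb/adposition lexicon and from the default keyword.

Sentences are realised by rendering the planned words to raw text and
re-tagging through the `RuleTagger`, so corpus and plan cannot drift; a
generation-time check asserts that extraction recovers the planted keys
and completeness flags exactly, and the manifest records them as the
oracle every exact-equality test consults. What the generator does *not*
emulate: real clinical syntax (subordination, coordination, anaphora),
tagger errors beyond the planted incomplete fraction, and entity-linking
ambiguity — so passing oracles demonstrate that the pipeline's rules are
implemented exactly, not that any particular parser would reach a given
yield on real guideline text.

Problem sizes in the test suite (200–500 sentences per corpus, 20 random
fixtures for the distillation oracle, ground truth of 202 triplets for the
evaluation scenario) are chosen so each oracle is decisive yet runs in
well under a second.

## Known limitations

No coreference or negation handling; no cross-sentence relations; no
entity linking to ontologies; extraction keeps only the first
subject/object per verb, so conjoined arguments yield one triplet. The
rule tagger's lexicon is small by design — real corpora need a statistical
parser behind the tagger contract, and absolute triplet yields will then
depend on that parser's version.
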