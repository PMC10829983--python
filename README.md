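# mlrkg — multi-level refined knowledge graphs from medical text

`mlrkg` builds knowledge graphs from plain-text medical articles by staged
refinement, for researchers and clinical informaticians who need a
transparent, auditable pipeline rather than a black-box extractor. Every
stage is a small, testable transformation on a table of
(subject, relation, object) triplets:

1. **Ingest** — segment articles into sentences and tag tokens through a
   pluggable tagger contract (a deterministic rule-based tagger ships with
   the package; any dependency parser can stand behind the same protocol).
2. **Extract** — one candidate triplet per verb: the subject is the first
   subject dependent of the verb, the object the first direct object,
   attribute, or prepositional object one adposition away (giving relations
   like *binds to*). Entities are multi-word phrases assembled from
   compound/modifier dependents.
3. **Refine** — a monotone cascade: keyword filtering, removal of
   incomplete triplets (any empty slot), deduplication on the normalised
   (source, edge, target) key, and optional expert-validation verdicts.
4. **Model** — a directed multigraph (networkx) with per-relation sub-KGs,
   `Source,Edge,Target` CSV interchange, and a self-contained interactive
   HTML export with joint-entity colouring.
5. **Joint analysis** — per-entity subject/object degrees over distinct
   triplets; a constraint `key(a, b)` selects entities occurring as subject
   in `a` and as object in `b` triplets (level *n* admits `2n + 1` such
   constraints).
6. **Distill** — the answer to a keyword query is the subgraph of all
   triplets touching a matching entity, expandable by hops.
7. **Evaluate** — frequency-based query-triplet prediction scored with
   recall, precision, F1, MRR, MAP and nDCG. MRR and MAP are normalised by
   ground-truth size (sum of reciprocal hit ranks over |truth|), and the
   DCG discount is `log2(rank)` with rank 1 undiscounted — deliberate,
   documented conventions of the evaluated system; textbook variants are
   available behind flags.

Synthetic corpora with *planted* ground truth (SVO structure, incomplete
and duplicate fractions, entity degrees, pair frequencies) make every
stage exactly testable offline — see `mlrkg.synthetic_fixtures`.

## Worked example

```bash
python examples/evaluate_chatbot.py
```

```
10 predictions vs 202 ground-truth triplets -> hits at ranks [1, 3]
     recall = 0.0099
  precision = 0.2
         f1 = 0.0189
        mrr = 0.0066
        map = 0.0083
        dcg = 1.6309
       idcg = 2.0
       ndcg = 0.8155
```

Two of ten predicted query triplets occur in the 202-triplet ground truth,
at ranks 1 and 3: recall is 2/202 = 0.0099 and precision 2/10 = 0.2. MRR
is (1/1 + 1/3)/202 = 0.0066; MAP weights the hits by relevance grades 1
and 2, (1·1/1 + 2·1/3)/202 = 0.0083. The binary-relevance DCG is
1 + 1/log2(3) = 1.6309 against an ideal of 1 + 1/log2(2) = 2, so
nDCG = 0.8155 — the ranking achieves 81.55 % of the ideal ordering.

The other examples each demonstrate one capability end to end:
`build_kg_from_text.py`, `refinement_cascade.py`, `joint_entities.py`,
`distill_keyword.py`.

A thin CLI chains the same stages from a shell:

```bash
mlrkg ingest --input article.txt --out tagged.jsonl
mlrkg extract --tagged tagged.jsonl --out triplets.csv
mlrkg refine --in triplets.csv --keywords kw.txt --out cleaned.csv
mlrkg build --in cleaned.csv --html kg.html --top-relations 10
mlrkg distill --in cleaned.csv --keyword asthma --out answer.csv
mlrkg evaluate --truth cleaned.csv --predict-k 10 --out metrics.csv
```

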