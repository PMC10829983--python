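"""Build a knowledge graph from a small plain-text article.

Segments the text into sentences with the built-in rule tagger, extracts
one SVO triplet per verb, keeps the complete ones and reports the most
frequent relations.  Each printed relation count says how many edges in
the graph carry that label.
"""
from mlrkg import (
    Document,
    RuleTagger,
    build_graph,
    extract_corpus,
    filter_complete,
    segment_sentences,
    top_relations,
)

TEXT = (
    "Budesonide reduces severe inflammation. "
    "Reslizumab binds to cell eosinophils. "
    "Tiotropium relieves persistent wheezing. "
    "Budesonide reduces nocturnal coughing. "
    "Severe wheezing persists."
)

doc = Document(doc_id="demo", body=TEXT)
sentences = segment_sentences(doc, RuleTagger())
table = extract_corpus(sentences)
complete = filter_complete(table)
kg = build_graph(complete)

print(f"{len(sentences)} sentences -> {table.row_count} candidate triplets, "
      f"{complete.row_count} complete")
print(f"graph: {len(kg.nodes)} entities, {kg.edge_count} relations")
for rc in top_relations(complete, 3):
    print(f"  {rc.count} x {rc.relation}")
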