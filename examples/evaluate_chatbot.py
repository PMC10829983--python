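"""Score predicted query triplets against a ground-truth table.

Ten frequency-ranked predictions are aligned with a 202-triplet ground
truth; exactly two predictions (ranks 1 and 3) occur in the truth.  The
metrics follow the ground-truth-normalised convention: MRR and MAP divide
reciprocal-rank sums by 202, not by the number of queries, and the DCG
discount is log2(rank) with rank 1 undiscounted.
"""
from mlrkg import align, evaluate
from mlrkg.synthetic_fixtures import paper_scenario

predicted, truth = paper_scenario()
hits = align(predicted, truth)
print(f"{len(predicted)} predictions vs {truth.row_count} ground-truth "
      f"triplets -> hits at ranks {[h.rank for h in hits]}")

report = evaluate(predicted, truth).rounded(4)
for name in ("recall", "precision", "f1", "mrr", "map", "dcg", "idcg", "ndcg"):
    print(f"  {name:>9} = {report[name]}")
print("recall is hits/202, precision hits/10; nDCG compares the achieved "
      "ranking against the ideal one (hits packed at the top).")
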