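"""Run the staged refinement cascade on a synthetic corpus.

The generator plants a known fraction of incomplete and duplicate
triplets; the cascade (keyword filter, completeness filter, deduplication)
must shrink the table monotonically, and the surviving counts are exactly
predictable from the planted fractions.
"""
from mlrkg import refine
from mlrkg.synthetic_fixtures import FixtureConfig, generate

config = FixtureConfig(
    n_sentences=500, p_incomplete=0.15, p_duplicate=0.10,
    keyword_fraction=0.4, seed=1,
)
_, table, manifest = generate(config)

stages = refine(table, keywords={manifest.keyword})
print("refinement cascade (rows per stage):")
for s in stages:
    print(f"  {s.stage_label:<18} {s.row_count}")
print(f"planted: {manifest.n_complete} complete of {manifest.n_sentences}, "
      f"{manifest.n_keyword_rows} keyword-bearing, "
      f"{manifest.n_distinct_complete_keys} distinct keys overall")
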