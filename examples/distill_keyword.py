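"""Distill the subgraph around a query keyword.

On a comorbidity-style graph, asking about "asthma" must surface every
condition linked to it in either direction — the distilled subgraph is
the answer a knowledge-graph chatbot would render.  The HTML export is a
self-contained interactive view (zoom, pan, drag).
"""
import tempfile
from pathlib import Path

from mlrkg import (
    DistillationQuery,
    build_graph,
    deduplicate,
    distill,
    export_interactive,
)
from mlrkg.synthetic_fixtures import comorbidity_table

kg = build_graph(deduplicate(comorbidity_table()))
sub = distill(kg, DistillationQuery(keyword="asthma", depth=1))

print(f"full graph: {len(kg.nodes)} entities, {kg.edge_count} relations")
print(f"distilled for 'asthma': {len(sub.nodes)} entities, "
      f"{sub.edge_count} relations")
for u, rel, v, _ in sub.edges:
    print(f"  {u} --[{rel}]--> {v}")

out = Path(tempfile.gettempdir()) / "asthma_distilled.html"
export_interactive(sub, out, title="Distilled: asthma")
print(f"interactive view written to {out}")
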