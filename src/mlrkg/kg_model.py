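"""Knowledge-graph construction and artefact I/O.

A :class:`KnowledgeGraph` wraps a :class:`networkx.MultiDiGraph`: nodes are
normalised entity labels (original-case surfaces kept in ``node_display``),
edges carry the relation label and sentence provenance.  Parallel edges are
deliberate — repeated (source, edge, target) rows survive until the
deduplication stage, and building a graph must not merge them silently.

Triplet tables interchange as CSV with the header ``Source,Edge,Target``
(RFC 4180 quoting, UTF-8), plus optional provenance columns.
"""
from __future__ import annotations

import csv
import html
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from ._types import Triplet, TripletTable, normalize
from .errors import ContractError, ParseError

#: Node colour classes for joint-version rendering.  Hues are fixed per
#: overlap class (blue default, orange for two-triplet joints, purple for
#: three or more) and overridable per export call.
DEFAULT_COLORS: dict[str, str] = {
    "default": "#1f78b4",
    "joint2": "#ff7f0e",
    "joint3": "#6a3d9a",
}

CSV_HEADER = ("Source", "Edge", "Target")


@dataclass
class KnowledgeGraph:
    """Directed multigraph over normalised entities."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    node_display: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, str, tuple[str, int]]]:
        """Edges as (source, relation, target, (doc_id, sent_index))."""
        return [
            (u, data["relation"], v, data.get("provenance", ("", -1)))
            for u, v, data in self.graph.edges(data=True)
        ]

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def edge_multiset(self) -> Counter:
        return Counter((u, r, v) for u, r, v, _ in self.edges)

    def add_triplet(self, t: Triplet) -> None:
        s, r, o = t.subject.normalized, t.relation, t.object.normalized
        self.node_display.setdefault(s, t.subject.surface)
        self.node_display.setdefault(o, t.object.surface)
        self.graph.add_edge(
            s, o, relation=r, provenance=(t.doc_id, t.sent_index)
        )

    def to_table(self, stage_label: str = "graph") -> TripletTable:
        rows = [
            Triplet.from_strings(
                self.node_display.get(u, u), r, self.node_display.get(v, v),
                doc_id=prov[0], sent_index=prov[1],
            )
            for u, r, v, prov in self.edges
        ]
        return TripletTable(rows=rows, stage_label=stage_label)


def build_graph(table: TripletTable) -> KnowledgeGraph:
    """One edge per row; all rows must be complete.

    An incomplete row is a contract violation (the completeness filter
    belongs upstream) and is reported with its row index.
    """
    kg = KnowledgeGraph()
    for i, t in enumerate(table):
        if not t.complete:
            raise ContractError(
                f"build_graph requires complete triplets; row {i} has "
                f"subject={t.subject.surface!r}, relation={t.relation!r}, "
                f"object={t.object.surface!r}"
            )
        kg.add_triplet(t)
    return kg


@dataclass(frozen=True)
class RelationCount:
    relation: str
    count: int


def top_relations(table: TripletTable, k: int) -> list[RelationCount]:
    """The k most frequent relation labels, ties broken lexicographically.

    Relations are compared as given (surface forms: "include" and
    "included" count separately).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = Counter(t.relation for t in table if t.relation)
    ranked = sorted(counts.items(), key=lambda rc: (-rc[1], rc[0]))
    return [RelationCount(r, c) for r, c in ranked[:k]]


def sub_kg_by_relation(kg: KnowledgeGraph, relation: str) -> KnowledgeGraph:
    """The sub-KG induced by one relation label (e.g. "associated with")."""
    sub = KnowledgeGraph()
    for u, r, v, prov in kg.edges:
        if r == relation:
            sub.node_display.setdefault(u, kg.node_display.get(u, u))
            sub.node_display.setdefault(v, kg.node_display.get(v, v))
            sub.graph.add_edge(u, v, relation=r, provenance=prov)
    return sub


# ---------------------------------------------------------------------------
# CSV interchange


def write_table(table: TripletTable, path: str | Path) -> None:
    """Write a triplet table as ``Source,Edge,Target`` CSV (RFC 4180).

    Provenance travels in optional DocId/SentIndex columns.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*CSV_HEADER, "DocId", "SentIndex"])
        for t in table:
            writer.writerow(
                [t.subject.surface, t.relation, t.object.surface,
                 t.doc_id, t.sent_index]
            )


def read_table(path: str | Path, stage_label: str = "loaded") -> TripletTable:
    """Read a triplet CSV; the three mandatory columns must be present."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row")
        if tuple(header[:3]) != CSV_HEADER:
            raise ParseError(
                f"{path}: expected header starting with "
                f"{','.join(CSV_HEADER)}, found {','.join(header) or '<empty>'}"
            )
        has_prov = len(header) >= 5 and header[3] == "DocId"
        rows = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(rec)} fields, expected >= 3"
                )
            doc_id, sent_index = "", -1
            if has_prov and len(rec) >= 5:
                doc_id = rec[3]
                try:
                    sent_index = int(rec[4])
                except ValueError:
                    sent_index = -1
            rows.append(
                Triplet.from_strings(rec[0], rec[1], rec[2], doc_id, sent_index)
            )
    return TripletTable(rows=rows, stage_label=stage_label)


# ---------------------------------------------------------------------------
# Interactive HTML export

_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
  body {{ margin: 0; font-family: sans-serif; }}
  #kg {{ width: 100vw; height: 100vh; display: block; }}
  .hint {{ position: fixed; top: 8px; left: 8px; color: #555;
           background: #ffffffcc; padding: 4px 8px; font-size: 13px; }}
</style>
</head>
<body>
<div class="hint">{title} &mdash; scroll to zoom, drag to pan or move nodes</div>
<canvas id="kg"></canvas>
<script id="kg-data" type="application/json">
{payload}
</script>
<script>
(function () {{
  var data = JSON.parse(document.getElementById("kg-data").textContent);
  var canvas = document.getElementById("kg");
  var ctx = canvas.getContext("2d");
  var scale = 1, tx = 0, ty = 0, drag = null, panning = false;
  var W, H;

  function resize() {{
    W = canvas.width = window.innerWidth;
    H = canvas.height = window.innerHeight;
  }}
  resize();
  window.addEventListener("resize", function () {{ resize(); draw(); }});

  // deterministic initial layout on a circle, then a few force steps
  var n = data.nodes.length;
  data.nodes.forEach(function (node, i) {{
    var a = 2 * Math.PI * i / Math.max(n, 1);
    node.x = 400 * Math.cos(a); node.y = 400 * Math.sin(a);
  }});
  var ix = {{}};
  data.nodes.forEach(function (node, i) {{ ix[node.id] = i; }});
  for (var it = 0; it < 150; it++) {{
    data.nodes.forEach(function (a) {{
      data.nodes.forEach(function (b) {{
        if (a === b) return;
        var dx = a.x - b.x, dy = a.y - b.y;
        var d2 = dx * dx + dy * dy + 0.01;
        a.x += 2000 * dx / d2; a.y += 2000 * dy / d2;
      }});
    }});
    data.edges.forEach(function (e) {{
      var a = data.nodes[ix[e.source]], b = data.nodes[ix[e.target]];
      var dx = b.x - a.x, dy = b.y - a.y;
      a.x += 0.02 * dx; a.y += 0.02 * dy;
      b.x -= 0.02 * dx; b.y -= 0.02 * dy;
    }});
  }}

  function toScreen(p) {{
    return [W / 2 + (p.x + tx) * scale, H / 2 + (p.y + ty) * scale];
  }}

  function draw() {{
    ctx.clearRect(0, 0, W, H);
    ctx.strokeStyle = "#999"; ctx.fillStyle = "#333";
    ctx.font = "12px sans-serif";
    data.edges.forEach(function (e) {{
      var a = toScreen(data.nodes[ix[e.source]]);
      var b = toScreen(data.nodes[ix[e.target]]);
      ctx.beginPath(); ctx.moveTo(a[0], a[1]); ctx.lineTo(b[0], b[1]);
      ctx.stroke();
      ctx.fillText(e.relation, (a[0] + b[0]) / 2, (a[1] + b[1]) / 2);
    }});
    data.nodes.forEach(function (node) {{
      var p = toScreen(node);
      ctx.beginPath(); ctx.arc(p[0], p[1], 7, 0, 2 * Math.PI);
      ctx.fillStyle = node.color; ctx.fill();
      ctx.fillStyle = "#000";
      ctx.fillText(node.label, p[0] + 9, p[1] + 4);
    }});
  }}

  canvas.addEventListener("wheel", function (ev) {{
    ev.preventDefault();
    scale *= ev.deltaY < 0 ? 1.1 : 0.9;
    draw();
  }});
  canvas.addEventListener("mousedown", function (ev) {{
    var mx = ev.clientX, my = ev.clientY;
    drag = null;
    data.nodes.forEach(function (node) {{
      var p = toScreen(node);
      if ((p[0] - mx) * (p[0] - mx) + (p[1] - my) * (p[1] - my) < 100)
        drag = node;
    }});
    if (!drag) panning = true;
  }});
  window.addEventListener("mousemove", function (ev) {{
    if (drag) {{
      drag.x += ev.movementX / scale; drag.y += ev.movementY / scale;
      draw();
    }} else if (panning) {{
      tx += ev.movementX / scale; ty += ev.movementY / scale;
      draw();
    }}
  }});
  window.addEventListener("mouseup", function () {{ drag = null; panning = false; }});
  draw();
}})();
</script>
</body>
</html>
"""


def export_interactive(
    kg: KnowledgeGraph,
    path: str | Path,
    colors: Mapping[str, str] | None = None,
    color_palette: Mapping[str, str] | None = None,
    title: str = "Knowledge graph",
) -> None:
    """Write a self-contained interactive HTML view of the graph.

    ``colors`` maps node -> colour class (``default``/``joint2``/``joint3``);
    unlisted nodes take the default class.  The document embeds the graph
    once as JSON (script tag ``kg-data``) and renders it with an inline
    zoom/pan/drag canvas script — no network resources.
    """
    palette = dict(DEFAULT_COLORS)
    if color_palette:
        palette.update(color_palette)
    colors = colors or {}
    bad = {c for c in colors.values() if c not in palette}
    if bad:
        raise ValueError(f"unknown colour classes: {sorted(bad)}")

    nodes = [
        {
            "id": node,
            "label": kg.node_display.get(node, node),
            "class": colors.get(node, "default"),
            "color": palette[colors.get(node, "default")],
        }
        for node in sorted(kg.nodes)
    ]
    edges = [
        {"source": u, "relation": r, "target": v}
        for u, r, v, _ in kg.edges
    ]
    payload = json.dumps({"nodes": nodes, "edges": edges}, indent=1)
    doc = _HTML_TEMPLATE.format(title=html.escape(title), payload=payload)
    Path(path).write_text(doc, encoding="utf-8")


def read_embedded_graph(path: str | Path) -> dict:
    """Parse the JSON payload back out of an exported HTML document."""
    text = Path(path).read_text(encoding="utf-8")
    start = text.index('<script id="kg-data" type="application/json">')
    start = text.index("\n", start) + 1
    end = text.index("</script>", start)
    return json.loads(text[start:end])


def plot_graph(
    kg: KnowledgeGraph,
    path: str | Path,
    colors: Mapping[str, str] | None = None,
    layout_seed: int = 42,
) -> None:
    """Static rendering of the graph (spring layout, fixed seed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = colors or {}
    pos = nx.spring_layout(kg.graph, seed=layout_seed)
    node_colors = [
        DEFAULT_COLORS[colors.get(n, "default")] for n in kg.graph.nodes
    ]
    fig, ax = plt.subplots(figsize=(10, 8))
    nx.draw_networkx(
        kg.graph, pos=pos, ax=ax, node_color=node_colors,
        labels={n: kg.node_display.get(n, n) for n in kg.graph.nodes},
        font_size=8, edge_color="#999999",
    )
    edge_labels = {
        (u, v): d["relation"]
        for u, v, d in kg.graph.edges(data=True)
    }
    nx.draw_networkx_edge_labels(
        kg.graph, pos=pos, ax=ax, edge_labels=edge_labels, font_size=7
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "KnowledgeGraph",
    "RelationCount",
    "DEFAULT_COLORS",
    "CSV_HEADER",
    "build_graph",
    "top_relations",
    "sub_kg_by_relation",
    "write_table",
    "read_table",
    "export_interactive",
    "read_embedded_graph",
    "plot_graph",
]
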