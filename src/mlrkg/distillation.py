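"""Keyword-centred knowledge distillation.

"Distillation" here is subgraph extraction, not model compression: given a
query keyword, return every triplet touching a matching entity, optionally
expanded outward by hops.  Edges are captured regardless of direction —
both what the keyword acts on and what acts on it belong to the answer.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._types import TripletTable, normalize
from .errors import QueryError
from .kg_model import KnowledgeGraph


@dataclass(frozen=True)
class DistillationQuery:
    keyword: str
    depth: int = 1
    match_mode: str = "substring"  # "substring" | "exact"

    def __post_init__(self) -> None:
        if not normalize(self.keyword):
            raise QueryError("distillation keyword is empty after normalisation")
        if self.depth < 1:
            raise QueryError(f"depth must be >= 1, got {self.depth}")
        if self.match_mode not in ("substring", "exact"):
            raise QueryError(f"unknown match_mode {self.match_mode!r}")


def _matches(node: str, keyword: str, mode: str) -> bool:
    return node == keyword if mode == "exact" else keyword in node


def distill(kg: KnowledgeGraph, query: DistillationQuery) -> KnowledgeGraph:
    """The keyword-centred subgraph of ``kg``.

    Depth 1 captures every edge whose source or target matches the keyword
    (case-insensitive, substring by default — "asthma" pulls "severe
    asthma").  Depth ``d`` expands edge-induced: any edge touching a node
    captured at a shallower depth is added, together with its endpoints.
    The result is always a subgraph of the input.
    """
    keyword = normalize(query.keyword)
    seeds = {
        n for n in kg.nodes if _matches(n, keyword, query.match_mode)
    }

    captured_nodes: set[str] = set(seeds)
    captured_edges: list[tuple[str, str, str, tuple[str, int]]] = []
    seen_edge_ids: set[int] = set()

    frontier = seeds
    for _ in range(query.depth):
        if not frontier:
            break
        next_frontier: set[str] = set()
        for eid, (u, r, v, prov) in enumerate(kg.edges):
            if eid in seen_edge_ids:
                continue
            if u in frontier or v in frontier:
                seen_edge_ids.add(eid)
                captured_edges.append((u, r, v, prov))
                for endpoint in (u, v):
                    if endpoint not in captured_nodes:
                        captured_nodes.add(endpoint)
                        next_frontier.add(endpoint)
        frontier = next_frontier

    sub = KnowledgeGraph()
    for node in sorted(captured_nodes):
        sub.graph.add_node(node)
        sub.node_display[node] = kg.node_display.get(node, node)
    for u, r, v, prov in captured_edges:
        sub.graph.add_edge(u, v, relation=r, provenance=prov)
    return sub


def distill_table(kg: KnowledgeGraph, query: DistillationQuery) -> TripletTable:
    """Same traversal, returned as a triplet table for CSV export."""
    return distill(kg, query).to_table(stage_label=f"distilled:{query.keyword}")


__all__ = ["DistillationQuery", "distill", "distill_table"]
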