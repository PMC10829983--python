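"""Graph construction, relation tallies, CSV dialect and HTML export."""
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlrkg import (
    Triplet,
    TripletTable,
    build_graph,
    read_table,
    sub_kg_by_relation,
    top_relations,
    write_table,
)
from mlrkg.errors import ContractError, ParseError
from mlrkg.kg_model import DEFAULT_COLORS, export_interactive, read_embedded_graph
from mlrkg.synthetic_fixtures import FixtureConfig, generate


class TestBuildGraph:
    def test_empty_table(self):
        kg = build_graph(TripletTable())
        assert kg.nodes == set()
        assert kg.edge_count == 0

    def test_sixteen_rows_give_sixteen_edges(self, guideline_table):
        kg = build_graph(guideline_table)
        assert kg.edge_count == 16

    def test_edge_multiset_matches_table(self, guideline_table):
        kg = build_graph(guideline_table)
        assert kg.edge_multiset() == Counter(
            (t.subject.normalized, t.relation, t.object.normalized)
            for t in guideline_table
        )

    def test_parallel_edges_not_merged(self):
        rows = [Triplet.from_strings("a", "r", "b")] * 3
        kg = build_graph(TripletTable(rows=rows))
        assert kg.edge_count == 3
        assert len(kg.nodes) == 2

    def test_incomplete_row_names_index(self):
        rows = [
            Triplet.from_strings("a", "r", "b"),
            Triplet.from_strings("a", "", "b"),
        ]
        with pytest.raises(ContractError, match="row 1"):
            build_graph(TripletTable(rows=rows))

    def test_node_count_bounded_by_twice_edges(self):
        _, table, _ = generate(FixtureConfig(n_sentences=80, seed=2))
        from mlrkg import filter_complete

        kg = build_graph(filter_complete(table))
        assert len(kg.nodes) <= 2 * kg.edge_count


class TestTopRelations:
    def test_empty_table(self):
        assert top_relations(TripletTable(), 5) == []

    def test_planted_frequencies_ranked(self):
        rows = (
            [Triplet.from_strings("a", "treats", "b")] * 5
            + [Triplet.from_strings("a", "causes", "b")] * 3
            + [Triplet.from_strings("a", "worsens", "b")]
        )
        top = top_relations(TripletTable(rows=rows), 2)
        assert [(rc.relation, rc.count) for rc in top] == [
            ("treats", 5), ("causes", 3),
        ]

    def test_surface_forms_counted_separately(self, guideline_table):
        top = top_relations(guideline_table, 20)
        labels = {rc.relation for rc in top}
        assert "include" in labels and "included" in labels

    def test_counts_conserve_edge_total(self, guideline_table):
        top = top_relations(guideline_table, 100)
        assert sum(rc.count for rc in top) == guideline_table.row_count

    def test_ties_break_lexicographically(self):
        rows = [
            Triplet.from_strings("a", "b-rel", "x"),
            Triplet.from_strings("a", "a-rel", "x"),
        ]
        top = top_relations(TripletTable(rows=rows), 2)
        assert [rc.relation for rc in top] == ["a-rel", "b-rel"]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_relations(TripletTable(), 0)


class TestSubKg:
    def test_absent_relation_gives_empty_graph(self, guideline_table):
        sub = sub_kg_by_relation(build_graph(guideline_table), "zzz")
        assert sub.edge_count == 0 and sub.nodes == set()

    def test_relation_slice(self, guideline_table):
        kg = build_graph(guideline_table)
        sub = sub_kg_by_relation(kg, "binds to")
        assert sub.edge_count == 1
        assert sub.nodes == {"reslizumab benralizumab", "cell eosinophils"}

    def test_union_over_relations_partitions_edges(self, guideline_table):
        kg = build_graph(guideline_table)
        relations = {r for _, r, _, _ in kg.edges}
        total = Counter()
        for rel in relations:
            total += sub_kg_by_relation(kg, rel).edge_multiset()
        assert total == kg.edge_multiset()


class TestCsvRoundTrip:
    def test_guideline_rows_survive_bit_exactly(self, guideline_table, tmp_path):
        p = tmp_path / "kg.csv"
        write_table(guideline_table, p)
        back = read_table(p)
        assert [
            (t.subject.surface, t.relation, t.object.surface) for t in back
        ] == [
            (t.subject.surface, t.relation, t.object.surface)
            for t in guideline_table
        ]
        header = p.read_text(encoding="utf-8").splitlines()[0]
        assert header.startswith("Source,Edge,Target")

    def test_empty_table_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_table(TripletTable(), p)
        back = read_table(p)
        assert back.row_count == 0

    @settings(deadline=None, max_examples=20)
    @given(
        rows=st.lists(
            st.tuples(
                st.text(
                    alphabet='abc ,"\n\'', min_size=1, max_size=8
                ).filter(lambda s: s.strip()),
                st.sampled_from(["treats", 'says "x, y"', "binds to"]),
                st.text(alphabet="xyz, ", min_size=1, max_size=8).filter(
                    lambda s: s.strip()
                ),
            ),
            max_size=10,
        )
    )
    def test_quoting_round_trip(self, tmp_path_factory, rows):
        table = TripletTable(
            rows=[Triplet.from_strings(s, r, o) for s, r, o in rows]
        )
        p = tmp_path_factory.mktemp("csv") / "q.csv"
        write_table(table, p)
        back = read_table(p)
        assert [
            (t.subject.surface, t.relation, t.object.surface) for t in back
        ] == [(s, r, o) for s, r, o in rows]

    def test_wrong_header_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("From,Rel,To\na,r,b\n")
        with pytest.raises(ParseError, match="From,Rel,To"):
            read_table(p)


class TestInteractiveExport:
    def test_empty_graph_still_valid_document(self, tmp_path):
        p = tmp_path / "empty.html"
        export_interactive(build_graph(TripletTable()), p)
        data = read_embedded_graph(p)
        assert data == {"nodes": [], "edges": []}

    def test_nodes_and_colors_embedded_once(self, tmp_path):
        rows = [
            Triplet.from_strings("a", "r", "b"),
            Triplet.from_strings("b", "r", "c"),
            Triplet.from_strings("c", "r", "d"),
        ]
        kg = build_graph(TripletTable(rows=rows))
        p = tmp_path / "kg.html"
        export_interactive(kg, p, colors={"b": "joint2", "c": "joint2"})
        data = read_embedded_graph(p)
        assert len(data["nodes"]) == 4  # a b c d
        assert len(data["edges"]) == 3
        orange = [n for n in data["nodes"] if n["class"] == "joint2"]
        assert {n["id"] for n in orange} == {"b", "c"}
        assert all(n["color"] == DEFAULT_COLORS["joint2"] for n in orange)

    def test_joint3_maps_to_purple_joint2_to_orange(self, tmp_path):
        kg = build_graph(
            TripletTable(rows=[Triplet.from_strings("a", "r", "b")])
        )
        p = tmp_path / "c.html"
        export_interactive(kg, p, colors={"a": "joint3", "b": "joint2"})
        by_id = {n["id"]: n for n in read_embedded_graph(p)["nodes"]}
        assert by_id["a"]["color"] == "#6a3d9a"
        assert by_id["b"]["color"] == "#ff7f0e"

    def test_unknown_class_rejected(self, tmp_path):
        kg = build_graph(
            TripletTable(rows=[Triplet.from_strings("a", "r", "b")])
        )
        with pytest.raises(ValueError, match="neon"):
            export_interactive(kg, tmp_path / "x.html", colors={"a": "neon"})
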