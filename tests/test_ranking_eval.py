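"""Ranking metrics under the ground-truth-normalised conventions."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlrkg import (
    RankedTriplet,
    Triplet,
    TripletTable,
    align,
    dcg_idcg_ndcg,
    evaluate,
    map_paper,
    mrr_paper,
    predict_query_triplets,
    recall_precision_f1,
)
from mlrkg.ranking_eval import round_half_up
from mlrkg.synthetic_fixtures import paper_scenario

TOL = 5e-5


class TestPrediction:
    def test_k_truncates_to_available_pairs(self):
        rows = [Triplet.from_strings("a", "r", "b")] * 2
        preds = predict_query_triplets(TripletTable(rows=rows), 10)
        assert len(preds) == 1
        assert preds[0].rank == 1

    def test_most_frequent_pair_ranks_first_with_supplied_relation(self):
        rows = (
            [Triplet.from_strings("Asthma", "worsens", "Asthma")] * 5
            + [Triplet.from_strings("Exacerbation", "suggests", "Asthma")] * 2
        )
        preds = predict_query_triplets(TripletTable(rows=rows), 2, relation="Am")
        assert preds[0].key == ("asthma", "am", "asthma")
        assert preds[1].key == ("exacerbation", "am", "asthma")

    def test_pairs_are_unordered_first_orientation_kept(self):
        rows = [
            Triplet.from_strings("b", "r", "a"),
            Triplet.from_strings("a", "r", "b"),
            Triplet.from_strings("c", "r", "d"),
        ]
        preds = predict_query_triplets(TripletTable(rows=rows), 2)
        assert preds[0].key == ("b", "am", "a")  # freq 2, first orientation

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            predict_query_triplets(TripletTable(), 0)


class TestAlign:
    def test_disjoint_sets_give_no_hits(self):
        preds = [RankedTriplet(("x", "r", "y"), 1)]
        truth = TripletTable(rows=[Triplet.from_strings("a", "r", "b")])
        assert align(preds, truth) == []

    def test_hits_keep_their_ranks(self):
        preds, truth = paper_scenario()
        hits = align(preds, truth)
        assert [h.rank for h in hits] == [1, 3]

    def test_agrees_with_set_intersection(self):
        preds, truth = paper_scenario()
        expected = {p.key for p in preds} & set(truth.keys())
        assert {h.key for h in align(preds, truth)} == expected


class TestRecallPrecisionF1:
    def test_worked_example(self):
        recall, precision, f1 = recall_precision_f1(2, 202, 10)
        assert round_half_up(recall) == 0.0099
        assert precision == pytest.approx(0.2)
        assert f1 == pytest.approx(2 * 0.2 * (2 / 202) / (0.2 + 2 / 202))

    def test_zero_hits(self):
        assert recall_precision_f1(0, 202, 10) == (0.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(
        n_truth=st.integers(1, 50),
        n_pred=st.integers(1, 50),
        data=st.data(),
    )
    def test_matches_brute_force_confusion_counts(self, n_truth, n_pred, data):
        n_hits = data.draw(st.integers(0, min(n_truth, n_pred)))
        recall, precision, _ = recall_precision_f1(n_hits, n_truth, n_pred)
        assert recall == pytest.approx(n_hits / n_truth)
        assert precision == pytest.approx(n_hits / n_pred)


class TestMrrMap:
    def test_mrr_worked_example(self):
        assert round_half_up(mrr_paper([1, 3], 202)) == 0.0066
        assert mrr_paper([1, 3], 202) == pytest.approx((4 / 3) / 202)

    def test_mrr_no_hits_and_identity(self):
        assert mrr_paper([], 202) == 0.0
        assert mrr_paper([1], 1) == 1.0

    def test_mrr_per_query_variant_is_textbook(self):
        assert mrr_paper([1, 3], 202, per_query=True) == pytest.approx(
            (1 + 1 / 3) / 2
        )

    def test_map_worked_example(self):
        assert round_half_up(map_paper([(1, 1), (3, 2)], 202)) == 0.0083
        assert map_paper([(1, 1), (3, 2)], 202) == pytest.approx((5 / 3) / 202)

    def test_map_invalid_truth_size(self):
        with pytest.raises(ValueError):
            map_paper([(1, 1)], 0)

    @settings(deadline=None, max_examples=30)
    @given(
        ranks=st.lists(st.integers(1, 30), unique=True, min_size=0, max_size=10),
        n_truth=st.integers(1, 300),
    )
    def test_unit_relevance_reduces_map_to_mrr(self, ranks, n_truth):
        assert map_paper([(r, 1) for r in ranks], n_truth) == pytest.approx(
            mrr_paper(ranks, n_truth)
        )

    @settings(deadline=None, max_examples=30)
    @given(
        ranks=st.lists(st.integers(1, 30), unique=True, min_size=1, max_size=10),
        n_truth=st.integers(1, 300),
    )
    def test_mrr_bounded_by_recall(self, ranks, n_truth):
        assert mrr_paper(ranks, n_truth) <= len(ranks) / n_truth + 1e-12


class TestDcg:
    def test_worked_example_vector(self):
        dcg, idcg, ndcg = dcg_idcg_ndcg([1, 0, 1, 0, 0, 0, 0, 0, 0, 0])
        assert dcg == pytest.approx(1 + 1 / math.log2(3))
        assert idcg == pytest.approx(2.0)
        assert round_half_up(ndcg) == 0.8155

    def test_all_zero_relevance(self):
        assert dcg_idcg_ndcg([0, 0, 0]) == (0.0, 0.0, 0.0)

    def test_rank_two_undiscounted_under_log2i(self):
        dcg, _, _ = dcg_idcg_ndcg([0, 1])
        assert dcg == pytest.approx(1.0)

    def test_alternative_discount_convention(self):
        dcg, _, _ = dcg_idcg_ndcg([1, 1], discount="log2(i+1)")
        assert dcg == pytest.approx(1 + 1 / math.log2(3))

    @settings(deadline=None, max_examples=30)
    @given(rels=st.lists(st.integers(0, 5), min_size=1, max_size=12))
    def test_descending_input_scores_ndcg_one(self, rels):
        ordered = sorted(rels, reverse=True)
        _, idcg, ndcg = dcg_idcg_ndcg(ordered)
        if idcg > 0:
            assert ndcg == pytest.approx(1.0)
        else:
            assert ndcg == 0.0

    def test_hits_packed_at_top_score_one(self):
        _, _, ndcg = dcg_idcg_ndcg([1, 1, 0, 0, 0])
        assert ndcg == pytest.approx(1.0)


class TestEvaluate:
    def test_scenario_reproduces_all_headline_numbers(self):
        preds, truth = paper_scenario()
        report = evaluate(preds, truth).rounded()
        assert report["recall"] == 0.0099
        assert report["precision"] == 0.2
        assert report["mrr"] == 0.0066
        assert report["map"] == 0.0083
        assert report["idcg"] == 2.0
        assert report["ndcg"] == 0.8155

    def test_empty_predictions_all_zero(self):
        _, truth = paper_scenario()
        report = evaluate([], truth)
        assert (report.recall, report.mrr, report.ndcg) == (0.0, 0.0, 0.0)

    def test_report_fields_equal_individual_metrics(self):
        preds, truth = paper_scenario()
        report = evaluate(preds, truth)
        hits = align(preds, truth)
        assert report.mrr == pytest.approx(
            mrr_paper([h.rank for h in hits], truth.row_count)
        )
        assert report.map == pytest.approx(
            map_paper([(h.rank, h.relevance) for h in hits], truth.row_count)
        )
        rel = [0.0] * 10
        for h in hits:
            rel[h.rank - 1] = 1.0
        assert (report.dcg, report.idcg, report.ndcg) == dcg_idcg_ndcg(rel)

    def test_pure_function_bit_identical(self):
        preds, truth = paper_scenario()
        assert evaluate(preds, truth) == evaluate(preds, truth)
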