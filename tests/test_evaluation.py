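import math

import numpy as np
import pytest

from atcpred import (
    MultiplicityHistogram,
    average_class_count,
    build_label_table,
    build_score_table,
    choose_m,
    compute_cp,
    coverage_lm,
    jackknife_evaluate,
    lm_from_order_accuracies,
    multiplicity_histogram,
    virtual_count,
)
from atcpred.predictor import RankedPrediction
from atcpred.synthetic import SyntheticConfig, simulate_benchmark


def _ranking(drug_id, order, method="interaction"):
    scores = tuple(float(len(order) - i) for i in range(len(order)))
    return RankedPrediction(drug_id, tuple(order), scores, method)


FULL = tuple(range(1, 15))


class TestVirtualCounting:
    def test_benchmark_breakdown(self):
        hist = MultiplicityHistogram({1: 3295, 2: 370, 3: 110, 4: 37, 5: 27, 6: 44})
        assert virtual_count(hist) == 4912
        assert hist.structural_count == 3883

    def test_comparison_breakdown(self):
        hist = MultiplicityHistogram({1: 1838, 2: 190, 3: 57, 4: 19, 5: 14, 6: 20})
        assert virtual_count(hist) == 2655
        assert hist.structural_count == 2138

    def test_all_single_class(self):
        assert virtual_count({1: 123}) == 123

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MultiplicityHistogram({1: -1})

    def test_histogram_matches_label_table(self):
        table = build_label_table([("d1", ["A", "N"]), ("d2", ["A"]), ("d3", ["B"])])
        hist = multiplicity_histogram(table)
        assert hist.counts == {1: 2, 2: 1}
        assert virtual_count(hist) == table.virtual_count() == 4


class TestAverageClassCount:
    def test_virtual_over_structural_ratio(self):
        hist = {1: 1838, 2: 190, 3: 57, 4: 19, 5: 14, 6: 20}
        an = virtual_count(hist) / MultiplicityHistogram(hist).structural_count
        assert an == pytest.approx(2655 / 2138)
        assert round(an, 2) == 1.24

    def test_single_label_drugs_give_one(self):
        table = build_label_table([("d1", ["A"]), ("d2", ["B"])])
        assert average_class_count(table) == 1.0

    def test_arithmetic_mean_of_multiplicities(self):
        table = build_label_table(
            [("d1", ["A"]), ("d2", ["A", "B"]), ("d3", ["A", "B", "C"])]
        )
        assert average_class_count(table) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_class_count([])


class TestChooseM:
    @pytest.mark.parametrize("an,m", [(2655 / 2138, 2), (1.0, 1), (2.5, 3), (1.24, 2)])
    def test_smallest_integer_at_least_an(self, an, m):
        assert choose_m(an) == m

    def test_an_below_one_rejected(self):
        with pytest.raises(ValueError):
            choose_m(0.9)


class TestComputeCp:
    def test_single_drug_hit_at_order_two(self):
        labels = build_label_table([("d1", ["B"])])
        cp = compute_cp([_ranking("d1", FULL)], labels)
        assert cp == [0, 1] + [0] * 12

    def test_multi_label_drug_hits_at_two_orders(self):
        labels = build_label_table([("d1", ["A", "C"])])
        order = (3, 1, 2) + tuple(range(4, 15))
        cp = compute_cp([_ranking("d1", order)], labels)
        assert cp[0] == 1 and cp[1] == 1 and cp[2] == 0

    def test_perfect_first_order(self):
        labels = build_label_table([(f"d{i}", ["A"]) for i in range(3)])
        preds = [_ranking(f"d{i}", FULL) for i in range(3)]
        cp = compute_cp(preds, labels)
        assert cp[0] == 3

    def test_unknown_drug_rejected(self):
        labels = build_label_table([("d1", ["A"])])
        with pytest.raises(ValueError, match="unknown"):
            compute_cp([_ranking("ghost", FULL)], labels)

    def test_short_rankings_contribute_nothing_beyond_their_length(self):
        labels = build_label_table([("d1", ["N"])])
        cp = compute_cp([_ranking("d1", (1, 2))], labels, length=14)
        assert cp == [0] * 14


class TestCoverage:
    def test_full_first_order_coverage(self):
        labels = build_label_table([("d1", ["A"]), ("d2", ["A"])])
        preds = [_ranking("d1", FULL), _ranking("d2", FULL)]
        assert coverage_lm(preds, labels, 1) == 1.0

    def test_by_hand_partial_coverage(self):
        # T=2, hits at orders 1 and 3; only one true class within m=2
        labels = build_label_table([("d1", ["A", "C"])])
        order = (1, 2, 3) + tuple(range(4, 15))
        assert coverage_lm([_ranking("d1", order)], labels, 2) == 0.5

    def test_m_below_one_rejected(self):
        labels = build_label_table([("d1", ["A"])])
        with pytest.raises(ValueError):
            coverage_lm([_ranking("d1", FULL)], labels, 0)

    def test_reconstruction_from_printed_accuracies(self):
        """(AC_1 + AC_2) / AN reproduces an overall two-order success rate."""
        an = 2655 / 2138
        l2 = lm_from_order_accuracies([0.6740, 0.2109], an, m=2)
        assert round(100 * l2, 2) == 71.26


class TestJackknife:
    def test_two_drug_mutual_hit(self):
        labels = build_label_table([("a", ["A"]), ("b", ["A"])])
        q = build_score_table("interaction", [("a", "b", 500)])
        preds, report = jackknife_evaluate(labels, q, method="interaction")
        assert [p.order[0] for p in preds] == [1, 1]
        assert report.ac[0] == 1.0
        assert report.n_queries == 2

    def test_run_twice_is_identical(self):
        cfg = SyntheticConfig(n_drugs=60, seed=5)
        labels, q, s, _ = simulate_benchmark(cfg)
        out1 = jackknife_evaluate(labels, q, s, method="integrated")
        out2 = jackknife_evaluate(labels, q, s, method="integrated")
        assert out1[0] == out2[0]
        assert out1[1].to_dict() == out2[1].to_dict()

    def test_isolated_drug_gets_all_tie_ranking(self):
        labels = build_label_table([("a", ["C"]), ("b", ["C"]), ("z", ["N"])])
        q = build_score_table("interaction", [("a", "b", 500)])
        preds, report = jackknife_evaluate(labels, q, method="interaction")
        z = next(p for p in preds if p.drug_id == "z")
        assert z.order == FULL
        assert z.method_used == "none"
        # its hit lands only where index-order tie-break puts class 10
        assert z.order[9] == 10
        assert report.method_breakdown == {"interaction": 2, "none": 1}

    def test_query_own_scores_never_leak(self):
        # b's only strong link is to itself via a duplicate-id edge; the
        # self-pair is already excluded at ingest, so b sees only the weak
        # cross-class edge and must not predict its own class first.
        import warnings

        labels = build_label_table([("a", ["A"]), ("b", ["N"]), ("c", ["A"])])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = build_score_table("interaction", [("b", "b", 1000), ("a", "b", 10)])
        preds, _ = jackknife_evaluate(labels, q, method="interaction")
        b = next(p for p in preds if p.drug_id == "b")
        assert b.order[0] == 1  # evidence points to class A, not its own N

    def test_fewer_than_two_drugs_rejected(self):
        labels = build_label_table([("a", ["A"])])
        q = build_score_table("interaction", [])
        with pytest.raises(ValueError):
            jackknife_evaluate(labels, q, method="interaction")

    def test_missing_required_table_rejected(self):
        labels = build_label_table([("a", ["A"]), ("b", ["A"])])
        with pytest.raises(ValueError):
            jackknife_evaluate(labels, None, None, method="interaction")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counting_identity_and_full_coverage(self, seed):
        """N * AN * L_m equals the sum of the first m per-order hit counts
        exactly, and full-length rankings recover every true class by
        order 14."""
        cfg = SyntheticConfig(n_drugs=80, p_within=0.3, p_between=0.05, seed=seed)
        labels, q, s, _ = simulate_benchmark(cfg)
        preds, report = jackknife_evaluate(labels, q, s, method="integrated")
        lhs = report.n_queries * report.an * report.l_m
        assert math.isclose(lhs, sum(report.cp[: report.m]), rel_tol=1e-12)
        assert coverage_lm(preds, labels, 14) == 1.0
        # hits cannot exceed the number of true memberships
        assert sum(report.cp) <= labels.virtual_count()

    def test_assortative_signal_beats_random_floor(self):
        """Strong within-class assortativity must lift first-order accuracy
        far above the label-independent floor."""
        base = dict(n_drugs=300, interaction_coverage=1.0, seed=9)
        strong = SyntheticConfig(p_within=1.0, p_between=0.0, **base)
        flat = SyntheticConfig(p_within=0.2, p_between=0.2, **base)
        ac1 = {}
        for name, cfg in [("strong", strong), ("flat", flat)]:
            labels, q, s, _ = simulate_benchmark(cfg)
            _, report = jackknife_evaluate(labels, q, s, method="interaction")
            ac1[name] = report.ac[0]
        assert ac1["strong"] > 0.7
        assert ac1["flat"] < 0.25
        assert ac1["strong"] > ac1["flat"] + 0.4

    def test_report_breakdown_sums_to_n(self):
        cfg = SyntheticConfig(n_drugs=100, interaction_coverage=0.5, seed=4)
        labels, q, s, _ = simulate_benchmark(cfg)
        _, report = jackknife_evaluate(labels, q, s, method="integrated")
        assert sum(report.method_breakdown.values()) == report.n_queries
        for j in range(14):
            assert sum(cp[j] for cp in report.cp_by_method.values()) == report.cp[j]
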