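"""Operating points, tie-corrected AUC, Youden selection, sum-score baselines."""

import numpy as np
import pandas as pd
import pytest

import pairscreen as ps
from pairscreen.roc import MetricError, OperatingPoint
from conftest import make_labeled_pair_data
from oracles import auc_double_loop, confusion_brute_force


def random_instance(rng, n, n_distinct=8):
    scores = rng.choice(np.linspace(0, 1, n_distinct), size=n)
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    return scores, labels


class TestAUC:
    def test_perfect_separation_is_one(self):
        assert ps.auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_pure_ties_is_half(self):
        assert ps.auc([0.5] * 6, [True, False, True, False, False, True]) == 0.5

    def test_single_class_fails(self):
        with pytest.raises(MetricError):
            ps.auc([0.1, 0.2], [True, True])

    def test_matches_double_loop_oracle_on_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores, labels = random_instance(rng, int(rng.integers(4, 31)))
            assert ps.auc(scores, labels) == pytest.approx(
                auc_double_loop(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            scores, labels = random_instance(rng, 100)
            assert ps.auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_trapezoid_equivalence_on_random_instances(self):
        """Rank AUC equals the trapezoidal area under the anchored ROC polygon."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            scores, labels = random_instance(rng, int(rng.integers(10, 201)))
            curve = ps.roc_curve(scores, labels)
            assert curve.auc == pytest.approx(curve.trapezoid_area(), abs=1e-12)


class TestOperatingPoints:
    def test_threshold_below_min_is_all_positive(self):
        pts = ps.operating_points([0.2, 0.5, 0.9], [True, False, True], [0.0])
        assert pts[0].sensitivity == 1.0 and pts[0].specificity == 0.0

    def test_perfect_separation_counts(self):
        pts = ps.operating_points(
            [0.9, 0.8, 0.2, 0.1], [True, True, False, False], [0.5]
        )
        p = pts[0]
        assert (p.tp, p.fp, p.tn, p.fn) == (2, 0, 2, 0)
        assert p.sensitivity == 1.0 and p.specificity == 1.0

    def test_tied_scores_match_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.choice([0.2, 0.5, 0.8], size=12)
        labels = rng.random(12) < 0.5
        labels[0], labels[1] = True, False
        for t in [0.1, 0.2, 0.5, 0.8, 0.9]:
            p = ps.operating_points(scores, labels, [t])[0]
            assert (p.tp, p.fp, p.tn, p.fn) == confusion_brute_force(scores, labels, t)

    def test_counts_conserve_n_and_roc_is_monotone(self):
        rng = np.random.default_rng(4)
        scores, labels = random_instance(rng, 150)
        thresholds = sorted(set(scores), reverse=True)
        pts = ps.operating_points(scores, labels, thresholds)
        for p in pts:
            assert p.n == 150
        tps = [p.tp for p in pts]
        fps = [p.fp for p in pts]
        assert tps == sorted(tps) and fps == sorted(fps)

    def test_single_class_fails(self):
        with pytest.raises(MetricError, match="single class"):
            ps.operating_points([0.1, 0.9], [False, False], [0.5])

    def test_youden_identity_holds_exactly(self):
        p = OperatingPoint(threshold=0.5, tp=30, fp=10, tn=50, fn=10)
        assert p.youden == pytest.approx(p.sensitivity + p.specificity - 1.0, abs=1e-15)


class TestCandidateThresholds:
    def test_distinct_probabilities_give_sixteen(self):
        model = ps.PairModel(ps.ItemPair(2, 4), 0.9, 0.55, -2.3, 1.0)
        assert len(ps.candidate_thresholds(model)) == 16

    def test_flat_model_gives_one(self):
        model = ps.PairModel(ps.ItemPair(2, 4), 0.0, 0.0, 0.0, 1.0)
        assert ps.candidate_thresholds(model) == [0.5]

    def test_equal_weights_give_seven(self):
        model = ps.PairModel(ps.ItemPair(2, 4), 1.0, 1.0, 0.0, 1.0)
        assert len(ps.candidate_thresholds(model)) == 7

    def test_descending_order(self):
        model = ps.PairModel(ps.ItemPair(2, 4), 0.7, 0.3, -1.0, 1.0)
        ts = ps.candidate_thresholds(model)
        assert ts == sorted(ts, reverse=True)

    def test_equal_weight_partitions_equal_sum_score_partitions(self):
        """With w1 = w2 > 0 the threshold lattice is exactly the 7 cutoff rules."""
        model = ps.PairModel(ps.ItemPair(2, 4), 0.8, 0.8, -2.0, 1.0)
        probs = model.pattern_probabilities()
        model_partitions = {
            frozenset(p for p, v in probs.items() if v >= t)
            for t in ps.candidate_thresholds(model)
        }
        sum_partitions = {
            frozenset((a, b) for a in range(4) for b in range(4) if a + b >= c)
            for c in range(7)
        }
        assert model_partitions == sum_partitions


class TestYoudenSelection:
    def make_point(self, sens_n, spec_n, threshold):
        # sens = sens_n/10 out of 10 positives, spec = spec_n/10 out of 10 negatives
        return OperatingPoint(
            threshold=threshold, tp=sens_n, fn=10 - sens_n, tn=spec_n, fp=10 - spec_n
        )

    def test_argmax(self):
        pts = [self.make_point(5, 5, 0.9), self.make_point(9, 8, 0.5), self.make_point(7, 7, 0.3)]
        assert ps.select_youden_threshold(pts) is pts[1]

    def test_tie_broken_toward_sensitivity(self):
        pts = [self.make_point(8, 9, 0.6), self.make_point(9, 8, 0.4)]
        chosen = ps.select_youden_threshold(pts)
        assert chosen.sensitivity == 0.9

    def test_singleton(self):
        pts = [self.make_point(5, 5, 0.5)]
        assert ps.select_youden_threshold(pts) is pts[0]

    def test_selected_dominates_all_candidates(self):
        rng = np.random.default_rng(5)
        scores, labels = random_instance(rng, 80)
        pts = ps.operating_points(scores, labels, sorted(set(scores)))
        chosen = ps.select_youden_threshold(pts)
        assert all(chosen.youden >= p.youden for p in pts)


class TestPredictiveValues:
    def test_perfect_specificity_gives_unit_ppv(self):
        p = OperatingPoint(threshold=0.5, tp=5, fn=5, tn=10, fp=0)
        ppv, _ = ps.predictive_values(p, 0.2)
        assert ppv == 1.0

    def test_uninformative_test_at_even_prevalence(self):
        p = OperatingPoint(threshold=0.5, tp=5, fn=5, tn=5, fp=5)
        ppv, npv = ps.predictive_values(p, 0.5)
        assert ppv == 0.5 and npv == 0.5

    def test_bayes_formula_matches_published_operating_point(self):
        """sens 0.934, spec 0.819 at 30.2% prevalence implies PPV near 0.690."""
        p = OperatingPoint(threshold=2, tp=934, fn=66, tn=819, fp=181)
        ppv, npv = ps.predictive_values(p, 0.302)
        assert ppv == pytest.approx(0.690, abs=2e-3)
        assert npv == pytest.approx(0.966, abs=2e-3)

    def test_count_based_ratios_match_bayes_at_sample_prevalence(self):
        p = OperatingPoint(threshold=0.5, tp=30, fp=20, tn=40, fn=10)
        prevalence = (p.tp + p.fn) / p.n
        ppv, npv = ps.predictive_values(p, prevalence)
        assert ppv == pytest.approx(p.ppv, abs=1e-12)
        assert npv == pytest.approx(p.npv, abs=1e-12)

    def test_undefined_ppv_flagged_not_zeroed(self):
        p = OperatingPoint(threshold=2.0, tp=0, fp=0, tn=10, fn=5)
        assert p.ppv is None


class TestSumScorePoints:
    def make_data(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 4, size=60)
        b = rng.integers(0, 4, size=60)
        labels = (a + b + rng.integers(0, 4, size=60)) >= 5
        labels[0], labels[1] = True, False
        return make_labeled_pair_data(a, b, labels, pair=(1, 2))

    def test_two_items_give_exactly_seven_rules(self):
        pts = ps.sum_score_points(self.make_data(), [1, 2])
        assert len(pts) == 7

    def test_cutoff_zero_is_all_positive(self):
        pts = ps.sum_score_points(self.make_data(), [1, 2])
        assert pts[0].sensitivity == 1.0 and pts[0].specificity == 0.0

    def test_highest_cutoff_flags_only_all_three_responders(self):
        data = make_labeled_pair_data([3, 3, 0], [3, 2, 0], [True, True, False], pair=(1, 2))
        pts = ps.sum_score_points(data, [1, 2])
        top = pts[-1]
        assert top.threshold == 6
        assert top.tp == 1 and top.fp == 0

    def test_empty_item_set_rejected(self):
        with pytest.raises(MetricError):
            ps.sum_score_points(self.make_data(), [])


class TestInstrument:
    def test_roundtrip_and_hash_stability(self, tmp_path):
        model = ps.PairModel(ps.ItemPair(2, 4), 0.9, 0.5, -2.0, 10.0)
        inst = ps.Instrument(kind="model", threshold=0.322, model=model)
        path = tmp_path / "instrument.json"
        inst.save(path)
        loaded = ps.Instrument.load(path)
        assert loaded == inst
        assert loaded.content_hash() == inst.content_hash()

    def test_sum_score_instrument_scores_subscale(self):
        inst = ps.Instrument(kind="sum_score", threshold=3.0, items=(1, 2))
        data = pd.DataFrame({"item1": [0, 3], "item2": [1, 2]})
        np.testing.assert_array_equal(inst.score(data), [1.0, 5.0])
        np.testing.assert_array_equal(inst.predict(data), [False, True])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ps.Instrument(kind="forest", threshold=0.5)
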