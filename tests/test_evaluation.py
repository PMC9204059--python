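"""Metrics, PR curves and the leakage-aware population split; sklearn serves
as an independent cross-check where its conventions coincide."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score, precision_recall_curve

from wingbeatid import (ConfusionMatrix, balanced_accuracy, evaluate_scores,
                        f1, population_split, pr_curve, precision, recall)


class TestClosedFormMetrics:
    def test_recall_precision_f1_hand_arithmetic(self):
        assert recall(ConfusionMatrix(tp=8, fp=0, tn=0, fn=2)) == 0.8
        assert precision(ConfusionMatrix(tp=8, fp=8, tn=0, fn=0)) == 0.5
        cm = ConfusionMatrix(tp=10, fp=10, tn=0, fn=0)  # precision .5, recall 1
        assert f1(cm) == pytest.approx(2 / 3)

    def test_zero_denominators_raise(self):
        with pytest.raises(ZeroDivisionError):
            recall(ConfusionMatrix(tp=0, fp=5, tn=5, fn=0))
        with pytest.raises(ZeroDivisionError):
            precision(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))

    def test_f1_is_one_iff_no_errors(self):
        assert f1(ConfusionMatrix(tp=7, fp=0, tn=3, fn=0)) == 1.0
        assert f1(ConfusionMatrix(tp=7, fp=1, tn=3, fn=0)) < 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, tn=0, fn=0)


class TestBalancedAccuracy:
    labels = np.array([0, 0, 0, 1, 1])

    def test_perfect_and_inverted_predictions(self):
        assert balanced_accuracy(self.labels, self.labels) == 1.0
        assert balanced_accuracy(self.labels, 1 - self.labels) == 0.0

    def test_all_positive_prediction_scores_half(self):
        assert balanced_accuracy(self.labels, np.ones(5, dtype=int)) == 0.5

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        assert balanced_accuracy(y, p) == pytest.approx(
            balanced_accuracy_score(y, p))

    def test_invariant_to_joint_class_renaming(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        assert balanced_accuracy(y, p) == pytest.approx(
            balanced_accuracy(1 - y, 1 - p))

    def test_equals_plain_accuracy_on_balanced_set(self):
        y = np.array([0] * 50 + [1] * 50)
        p = np.random.default_rng(2).integers(0, 2, 100)
        assert balanced_accuracy(y, p) == pytest.approx(np.mean(y == p))

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.ones(5), np.ones(5))


class TestPRCurve:
    def test_perfect_separation_contains_the_ideal_point(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        curve = pr_curve(scores, labels)
        assert any(p == 1.0 and r == 1.0
                   for p, r in zip(curve.precision, curve.recall))

    def test_recall_is_non_decreasing_along_the_sweep(self):
        rng = np.random.default_rng(3)
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        curve = pr_curve(scores, labels)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_random_scores_precision_near_prevalence_at_high_recall(self):
        rng = np.random.default_rng(4)
        n = 10_000
        labels = (rng.random(n) < 0.3).astype(int)
        scores = rng.random(n)  # independent of labels
        curve = pr_curve(scores, labels)
        tail = curve.precision[curve.recall > 0.95]
        assert abs(tail.mean() - 0.3) < 0.02

    def test_agrees_with_sklearn_on_shared_points(self):
        rng = np.random.default_rng(5)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        curve = pr_curve(scores, labels)
        sk_p, sk_r, sk_t = precision_recall_curve(labels, scores)
        ours = {round(t, 12): (p, r) for t, p, r in
                zip(curve.thresholds, curve.precision, curve.recall)}
        for p, r, t in zip(sk_p[:-1], sk_r[:-1], sk_t):
            # sklearn thresholds predict positive at score >= t, like ours
            if round(t, 12) in ours:
                op, orr = ours[round(t, 12)]
                assert op == pytest.approx(p) and orr == pytest.approx(r)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([0.5, 0.6]), np.array([1, 1]))


def _manifest(sizes: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    for (species, pop), n in sizes.items():
        for i in range(n):
            rows.append({"record_id": f"{pop}_{i}", "path": "",
                         "species": species, "population": pop,
                         "timestamp": "", "true_f0": 200.0})
    return pd.DataFrame(rows)


class TestPopulationSplit:
    def test_larger_population_goes_to_training_side(self):
        manifest = _manifest({("DM", "DM_A"): 120, ("DM", "DM_B"): 80,
                              ("SWD", "SWD_A"): 150, ("SWD", "SWD_B"): 90})
        plan = population_split(manifest, seed=0)
        assert plan.population_split == {"DM_A": "train", "DM_B": "test",
                                         "SWD_A": "train", "SWD_B": "test"}

    def test_validation_is_20_percent_of_training_side(self):
        manifest = _manifest({("DM", "DM_A"): 500, ("DM", "DM_B"): 100,
                              ("SWD", "SWD_A"): 500, ("SWD", "SWD_B"): 100})
        plan = population_split(manifest, seed=1)
        n_val = len(plan.records("validation"))
        assert abs(n_val - 200) <= 1
        assert len(plan.records("train")) + n_val == 1000

    def test_no_record_or_population_straddles_splits(self):
        manifest = _manifest({("DM", "DM_A"): 60, ("DM", "DM_B"): 40,
                              ("SWD", "SWD_A"): 70, ("SWD", "SWD_B"): 30})
        plan = population_split(manifest, seed=2)
        frame = plan.to_frame()
        assert frame["record_id"].is_unique
        pop_of = dict(zip(manifest["record_id"], manifest["population"]))
        for pop in ["DM_A", "DM_B", "SWD_A", "SWD_B"]:
            splits = {s for rid, s in plan.assignments.items()
                      if pop_of[rid] == pop}
            assert splits <= {"train", "validation"} or splits == {"test"}

    def test_same_seed_is_idempotent(self):
        manifest = _manifest({("DM", "DM_A"): 60, ("DM", "DM_B"): 40,
                              ("SWD", "SWD_A"): 70, ("SWD", "SWD_B"): 30})
        assert population_split(manifest, seed=3).assignments == \
            population_split(manifest, seed=3).assignments

    def test_single_population_species_errors(self):
        manifest = _manifest({("DM", "DM_A"): 60,
                              ("SWD", "SWD_A"): 70, ("SWD", "SWD_B"): 30})
        with pytest.raises(ValueError):
            population_split(manifest, seed=4)

    def test_false_triggers_are_left_out_of_the_plan(self):
        manifest = _manifest({("DM", "DM_A"): 10, ("DM", "DM_B"): 5,
                              ("SWD", "SWD_A"): 10, ("SWD", "SWD_B"): 5,
                              ("unknown", "noise"): 7})
        plan = population_split(manifest, seed=5)
        assert len(plan.assignments) == 30


class TestEvaluateScores:
    def test_oracle_scores_give_perfect_metrics(self):
        labels = np.array([0, 1, 0, 1, 1])
        report = evaluate_scores(labels.astype(float), labels, threshold=0.5)
        assert report.balanced_accuracy == 1.0 and report.f1 == 1.0

    def test_constant_score_on_balanced_set_gives_half(self):
        labels = np.array([0, 0, 1, 1])
        report = evaluate_scores(np.full(4, 0.7), labels, threshold=0.5)
        assert report.balanced_accuracy == 0.5

    def test_report_consistent_with_its_own_confusion_matrix(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 100)
        scores = np.clip(labels * 0.4 + rng.normal(0.3, 0.25, 100), 0, 1)
        report = evaluate_scores(scores, labels, threshold=0.5)
        cm = report.confusion
        assert report.precision == pytest.approx(precision(cm))
        assert report.recall == pytest.approx(recall(cm))
        assert report.f1 == pytest.approx(f1(cm))
        assert report.balanced_accuracy == pytest.approx(
            0.5 * (cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp)))

    def test_empty_set_and_bad_threshold_error(self):
        with pytest.raises(ValueError):
            evaluate_scores(np.array([]), np.array([]), 0.5)
        with pytest.raises(ValueError):
            evaluate_scores(np.array([0.5]), np.array([1]), 1.5)

    def test_undefined_precision_is_flagged_not_silent(self):
        labels = np.array([0, 1])
        report = evaluate_scores(np.array([0.1, 0.2]), labels, threshold=0.9)
        assert report.precision == 0.0
        assert any("precision undefined" in f for f in report.flags)

    def test_confusion_frame_orientation(self):
        cm = ConfusionMatrix(tp=1, fp=2, tn=3, fn=4)
        frame = cm.to_frame()
        assert frame.loc["DM", "DM"] == 3      # true DM predicted DM
        assert frame.loc["DM", "SWD"] == 2     # false positive
        assert frame.loc["SWD", "DM"] == 4     # false negative
        assert frame.loc["SWD", "SWD"] == 1
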