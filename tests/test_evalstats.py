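"""Metric identities and oracles: IoU, PR/F1, AP, AUC, Mann-Whitney U."""

import numpy as np
import pytest
from scipy import stats as sps

from sowestrus.evalstats import (
    ConfusionCounts,
    accuracy_f1,
    confusion_from_labels,
    group_summary,
    iou,
    map50,
    mann_whitney_u,
    match_detections,
    precision_recall,
    rank_biserial,
    roc_pr_auc,
)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_half_offset_unit_squares(self):
        # overlap 0.5, union 1.5
        assert iou((0, 0, 1, 1), (0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)

    def test_zero_area_box_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert iou((0, 0, 0, 10), (0, 0, 10, 10)) == 0.0


class TestConfusionMetrics:
    def test_worked_counts(self):
        p, r = precision_recall(ConfusionCounts(tp=8, fp=2, fn=2, tn=0))
        assert (p, r) == (0.8, 0.8)
        acc, f1 = accuracy_f1(ConfusionCounts(tp=50, tn=40, fp=5, fn=5))
        assert acc == pytest.approx(0.9)

    def test_perfect_counts(self):
        assert precision_recall(ConfusionCounts(tp=7, fp=0, fn=0, tn=3)) == (1.0, 1.0)

    def test_f1_equals_p_when_p_equals_r(self):
        c = ConfusionCounts(tp=6, fp=2, fn=2, tn=1)
        p, r = precision_recall(c)
        assert p == r
        _, f1 = accuracy_f1(c)
        assert f1 == pytest.approx(p)

    def test_zero_denominator_flags_nan(self):
        with pytest.warns(UserWarning):
            p, _ = precision_recall(ConfusionCounts(tp=0, fp=0, fn=3, tn=2))
        assert np.isnan(p)

    def test_grid_against_direct_formulas(self):
        for tp in range(0, 4):
            for fp in range(0, 4):
                for fn in range(0, 4):
                    for tn in range(0, 4):
                        if tp + fp + fn + tn == 0:
                            continue
                        c = ConfusionCounts(tp, fp, fn, tn)
                        import warnings

                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            acc, f1 = accuracy_f1(c)
                            p, r = precision_recall(c)
                        assert acc == (tp + tn) / (tp + fp + fn + tn)
                        if tp + fp and tp + fn and p + r:
                            assert f1 == pytest.approx(2 * p * r / (p + r))
                        assert 0 <= acc <= 1

    def test_counts_conserved(self):
        y_true = [1, 0, 1, 1, 0, 0]
        y_pred = [1, 1, 0, 1, 0, 0]
        c = confusion_from_labels(y_true, y_pred)
        assert c.total == len(y_true)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 2)


class TestAveragePrecision:
    def test_perfect_detector(self):
        matches = [(0.9, True), (0.5, True), (0.7, True)]
        assert map50(matches, 3) == 1.0

    def test_no_predictions(self):
        assert map50([], 5) == 0.0

    def test_three_prediction_hand_example(self):
        """Ranked TP, FP, TP over 2 truths: AP = 0.5*1 + 0.5*(2/3) = 5/6."""
        matches = [(0.9, True), (0.8, False), (0.7, True)]
        assert map50(matches, 2) == pytest.approx(5 / 6)

    def test_invariant_to_monotone_confidence_transform(self, rng):
        matches = [(float(c), bool(h)) for c, h in zip(rng.random(20), rng.random(20) > 0.4)]
        ap1 = map50(matches, 12)
        transformed = [(2.0 * c**3 + 1.0, h) for c, h in matches]
        assert map50(transformed, 12) == pytest.approx(ap1)

    def test_undefined_without_truths(self):
        with pytest.warns(UserWarning):
            assert np.isnan(map50([(0.5, False)], 0))

    def test_greedy_matching_counts_duplicates_as_fp(self):
        truth = [(0, 0, 10, 10)]
        preds = [((0, 0, 10, 10), 0.9), ((1, 1, 11, 11), 0.8)]
        res = match_detections(preds, truth)
        assert res == [(0.9, True), (0.8, False)]


class TestAUC:
    def test_perfect_separation(self):
        auc_roc, auc_pr = roc_pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (auc_roc, auc_pr) == (1.0, 1.0)

    def test_chance_level_for_independent_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        auc_roc, _ = roc_pr_auc(scores, labels)
        assert abs(auc_roc - 0.5) < 0.03

    def test_rank_statistic_identity(self, rng):
        """AUC-ROC equals U'/(n1*n2) where U' counts positive-over-negative wins."""
        for _ in range(5):
            n1, n2 = 23, 31
            pos = rng.normal(0.6, 0.3, n1)
            neg = rng.normal(0.3, 0.3, n2)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones(n1), np.zeros(n2)]
            auc_roc, _ = roc_pr_auc(scores, labels)
            u_prime = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert auc_roc == pytest.approx(u_prime / (n1 * n2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_auc([0.1, 0.9], [1, 1])


class TestMannWhitney:
    def test_complete_separation_gives_zero(self):
        assert mann_whitney_u([1, 2, 3], [10, 11, 12]) == 0.0

    def test_identical_samples_midpoint(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney_u(x, x) == len(x) ** 2 / 2

    def test_brute_force_pair_count_oracle(self, rng):
        x1 = rng.normal(size=5)
        x2 = rng.normal(size=5)
        u1 = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in x1 for b in x2
        )
        assert mann_whitney_u(x1, x2) == pytest.approx(min(u1, 25 - u1))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestRankBiserial:
    def test_published_aspect_ratio_effect_size(self):
        assert round(rank_biserial(826, 148, 350), 2) == 0.97

    def test_no_effect_at_midpoint(self):
        assert rank_biserial(148 * 350 / 2, 148, 350) == 0.0

    def test_complete_separation(self):
        assert rank_biserial(0, 10, 20) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial(1000, 10, 10)


def test_group_summary_reports_table_style_statistics(rng):
    est = {"aspect_ratio": rng.normal(0.68, 0.27, 148)}
    non = {"aspect_ratio": rng.normal(0.97, 0.31, 350)}
    table = group_summary(est, non)
    row = table.iloc[0]
    assert row["U"] <= 148 * 350 / 2
    assert 0 <= row["rank_biserial_r"] <= 1
    assert row["estrus_mean"] == pytest.approx(0.68, abs=0.1)
    assert row["mannwhitney_p"] < 0.001
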