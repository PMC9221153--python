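"""Tolerability aggregation, severity classes, ROC/accuracy/confusion
metrics and Kruskal-Wallis."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from conftest import pair_counting_auc
from gapmertox.tolerability import (
    accuracy_vs_cutoff,
    aggregate_tolerability,
    binary_label,
    classification_report,
    classify_severity,
    kruskal_wallis,
    roc_analysis,
)


class TestAggregate:
    def test_extremes(self):
        assert aggregate_tolerability([(4, 4, 4, 4, 4)]) == 20.0
        assert aggregate_tolerability([(0, 0, 0, 0, 0)]) == 0.0

    def test_group_mean(self):
        assert aggregate_tolerability([(1, 0, 2, 0, 0), (0, 0, 1, 0, 0)]) == 2.0

    @pytest.mark.parametrize("bad", [(5, 0, 0, 0, 0), (-1, 0, 0, 0, 0), (0.5, 0, 0, 0, 0)])
    def test_invalid_category_rejected(self, bad):
        with pytest.raises(ValueError):
            aggregate_tolerability([bad])

    def test_wrong_category_count_rejected(self):
        with pytest.raises(ValueError):
            aggregate_tolerability([(1, 2, 3)])


class TestSeverity:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, "mild"),
            (0.2, "mild"),
            (3.99, "mild"),
            (4.0, "moderate"),
            (6.99, "moderate"),
            (7.0, "marked"),
            (13.0, "marked"),
            (18.0, "marked"),
            (18.01, "severe"),
            (20.0, "severe"),
        ],
    )
    def test_bins(self, score, expected):
        assert classify_severity(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(20.5)

    @given(st.floats(min_value=0, max_value=19.99), st.floats(min_value=0.001, max_value=5))
    @settings(max_examples=200, deadline=None)
    def test_monotone(self, score, delta):
        order = ["mild", "moderate", "marked", "severe"]
        hi = min(score + delta, 20.0)
        assert order.index(classify_severity(hi)) >= order.index(
            classify_severity(score)
        )

    @pytest.mark.parametrize(
        "score,expected",
        [(4.0, "acceptable"), (4.5, "toxic"), (0.0, "acceptable"), (20.0, "toxic")],
    )
    def test_binary_boundary_at_or_below_4(self, score, expected):
        assert binary_label(score) == expected


class TestRoc:
    def test_perfect_separation(self):
        scores = [10, 20, 30, 80, 90, 100]
        labels = ["toxic"] * 3 + ["acceptable"] * 3
        assert roc_analysis(scores, labels).auc == pytest.approx(1.0)

    def test_constant_predictor_is_chance(self):
        labels = ["toxic", "acceptable"] * 5
        assert roc_analysis([50] * 10, labels).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1, 2, 3], ["toxic"] * 3)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 10, size=n).astype(float)  # ties likely
            toxic = rng.random(n) < 0.5
            if toxic.all() or not toxic.any():
                continue
            auc = roc_analysis(scores, toxic).auc
            assert auc == pytest.approx(pair_counting_auc(scores, toxic), abs=1e-12)

    def test_flipping_predictor_complements_auc(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 25
            scores = rng.normal(size=n)
            toxic = rng.random(n) < 0.4
            if toxic.all() or not toxic.any():
                continue
            a1 = roc_analysis(scores, toxic).auc
            a2 = roc_analysis(-scores, toxic).auc
            assert a1 + a2 == pytest.approx(1.0)


class TestAccuracyCutoff:
    def test_perfect_predictor_on_point_grid(self):
        labels = ["acceptable", "toxic", "acceptable", "toxic"]
        pred = [1.0, 0.0, 1.0, 0.0]
        curve = accuracy_vs_cutoff(pred, labels, cutoff_grid=[0.5])
        assert curve.max_accuracy == pytest.approx(1.0)

    def test_cutoff_below_all_scores_predicts_all_acceptable(self):
        labels = ["acceptable"] * 6 + ["toxic"] * 4
        pred = np.linspace(50, 150, 10)
        curve = accuracy_vs_cutoff(pred, labels, cutoff_grid=[-np.inf])
        assert curve.accuracy[0] == pytest.approx(0.6)  # class prevalence

    def test_plateau_midpoint_reported(self):
        # acceptable iff score > 70 with a gap between 65 and 75:
        # every integer cutoff in 65..74 classifies perfectly.
        labels = ["toxic"] * 3 + ["acceptable"] * 3
        pred = [50.0, 60.0, 65.0, 75.0, 80.0, 90.0]
        curve = accuracy_vs_cutoff(pred, labels)
        assert curve.max_accuracy == pytest.approx(1.0)
        assert curve.optimal_cutoff == pytest.approx(69.5)

    def test_optimal_accuracy_dominates_grid(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(0, 200, 40)
        toxic = pred + rng.normal(0, 60, 40) < 100
        if toxic.all() or not toxic.any():
            pytest.skip("degenerate draw")
        curve = accuracy_vs_cutoff(pred, toxic)
        rep = classification_report(pred, toxic, curve.optimal_cutoff)
        assert rep.accuracy >= curve.accuracy.max() - 1e-12
        assert (curve.accuracy <= curve.max_accuracy + 1e-12).all()


class TestClassificationReport:
    def test_hand_counted_confusion_table(self):
        """10 ASOs arranged to give TP=3, FP=1, TN=5, FN=1 at cutoff 70."""
        pred = [50, 55, 60, 65, 75, 80, 85, 90, 95, 100]
        toxic = [True, True, True, False, True, False, False, False, False, False]
        rep = classification_report(pred, toxic, cutoff=70)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 5, 1)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.npv == pytest.approx(5 / 6)
        assert rep.ppv == pytest.approx(3 / 4)

    def test_perfect_predictor(self):
        pred = [10, 20, 90, 95]
        toxic = [True, True, False, False]
        rep = classification_report(pred, toxic, cutoff=50)
        assert rep.accuracy == rep.ppv == rep.npv == 1.0

    def test_cutoff_below_all_scores_gives_zero_sensitivity(self):
        pred = [60, 70, 80, 90]
        toxic = [True, False, True, False]
        with pytest.warns(UserWarning, match="PPV"):
            rep = classification_report(pred, toxic, cutoff=10)
        assert rep.sensitivity == 0.0
        assert np.isnan(rep.ppv)

    def test_metrics_recompute_from_counts(self):
        rng = np.random.default_rng(8)
        pred = rng.uniform(0, 200, 30)
        toxic = rng.random(30) < 0.4
        if toxic.all() or not toxic.any():
            pytest.skip("degenerate draw")
        rep = classification_report(pred, toxic, cutoff=100)
        n = rep.tp + rep.fp + rep.tn + rep.fn
        assert n == 30
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / n)
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))


class TestKruskalWallis:
    def test_identical_group_composition_gives_zero_h(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_separated_groups_match_rank_sum_oracle(self):
        groups = [[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]
        h, p = kruskal_wallis(groups)
        h_oracle, p_oracle = self._oracle(groups)
        assert h == pytest.approx(h_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_tie_correction_matches_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            groups = [
                list(rng.integers(0, 4, size=rng.integers(3, 8)).astype(float))
                for _ in range(3)
            ]
            flat = np.concatenate(groups)
            if np.ptp(flat) == 0:
                continue
            h, p = kruskal_wallis(groups)
            h_oracle, p_oracle = self._oracle(groups)
            assert h == pytest.approx(h_oracle, abs=1e-10)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    @staticmethod
    def _oracle(groups):
        """Independently coded tie-corrected rank-sum formula."""
        flat = np.concatenate([np.asarray(g, float) for g in groups])
        n = len(flat)
        ranks = scipy.stats.rankdata(flat)
        h = 0.0
        start = 0
        for g in groups:
            r = ranks[start : start + len(g)]
            h += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(flat, return_counts=True)
        correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
        h /= correction
        p = scipy.stats.chi2.sf(h, len(groups) - 1)
        return h, p
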