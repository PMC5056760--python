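"""Metrics, ROC/PR curves and cross-validation."""

import numpy as np
import pytest

from helpers import auroc_pair_counting
from m6asite import evaluation as ev
from m6asite.evaluation import ConfusionCounts


class TestConfusionMetrics:
    def test_printed_formula_example(self):
        c = ConfusionCounts(tp=40, tn=40, fp=10, fn=10)
        assert ev.mcc(c) == pytest.approx(0.6)
        assert ev.sensitivity(c) == pytest.approx(0.8)
        assert ev.specificity(c) == pytest.approx(0.8)

    def test_perfect_prediction(self):
        c = ConfusionCounts(tp=7, tn=13, fp=0, fn=0)
        assert (ev.sensitivity(c), ev.specificity(c), ev.mcc(c)) == (1.0, 1.0, 1.0)

    def test_all_positive_predictor(self):
        c = ConfusionCounts(tp=5, tn=0, fp=9, fn=0)
        assert ev.specificity(c) == 0.0

    def test_degenerate_denominators_return_zero(self):
        assert ev.mcc(ConfusionCounts(0, 0, 0, 0)) == 0.0
        assert ev.sensitivity(ConfusionCounts(0, 5, 5, 0)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_random_confusion_matrices_against_direct_formulas(self):
        import math

        rng = np.random.default_rng(0)
        for _ in range(300):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            c = ConfusionCounts(tp, tn, fp, fn)
            assert ev.sensitivity(c) == (tp / (tp + fn) if tp + fn else 0.0)
            assert ev.specificity(c) == (tn / (tn + fp) if tn + fp else 0.0)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
            assert ev.mcc(c) == pytest.approx(expected)

    def test_confusion_at_threshold(self):
        scores = np.array([0.1, 0.6, 0.4, 0.9])
        labels = np.array([0, 1, 0, 1])
        c = ev.confusion_at_threshold(scores, labels, 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)


class TestRoc:
    def test_perfect_scorer(self):
        labels = np.repeat([0, 1], 50)
        assert ev.auroc(labels.astype(float), labels) == 1.0

    def test_complete_ties_give_half(self):
        labels = np.repeat([0, 1], 50)
        assert ev.auroc(np.zeros(100), labels) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse scores so ties occur
            scores = rng.integers(0, 8, size=n).astype(float)
            assert ev.auroc(scores, labels) == \
                pytest.approx(auroc_pair_counting(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auroc(np.ones(5), np.ones(5, dtype=int))

    def test_curve_endpoints(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 30)
        fpr, tpr, _ = ev.roc_points(rng.normal(size=60), labels)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)


class TestPr:
    def test_perfect_separation(self):
        labels = np.repeat([0, 1], 40)
        assert ev.aupr(labels.astype(float), labels) == 1.0

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(3)
        n_pos, ratio = 2000, 10
        labels = np.repeat([1, 0], [n_pos, ratio * n_pos])
        scores = rng.uniform(size=len(labels))
        assert ev.aupr(scores, labels) == pytest.approx(1 / 11, abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        scores = rng.normal(size=200)
        assert ev.aupr(scores, labels) == \
            pytest.approx(ev.aupr(np.exp(3 * scores), labels))

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            ev.aupr(np.arange(4.0), np.zeros(4, dtype=int))


class TestReports:
    def test_fpr_is_one_minus_specificity(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 100)
        scores = rng.normal(size=200) + labels
        report = ev.evaluate_scores(
            scores, labels, thresholds={"high": 1.2, "moderate": 0.5, "low": -0.1}
        )
        for level, m in report.threshold_metrics.items():
            c = ev.confusion_at_threshold(scores, labels, m["threshold"])
            fpr = c.fp / (c.fp + c.tn)
            assert fpr == pytest.approx(1.0 - m["specificity"])

    def test_stringency_ordering_of_specificity(self, null_pipeline):
        metrics = null_pipeline["report"].threshold_metrics
        assert metrics["high"]["specificity"] >= metrics["moderate"]["specificity"]
        assert metrics["moderate"]["specificity"] >= metrics["low"]["specificity"]

    def test_report_serialization(self, tmp_path):
        labels = np.repeat([0, 1], 50)
        report = ev.evaluate_scores(np.arange(100.0), labels)
        report.to_json(tmp_path / "report.json")
        report.curves_to_tsv(tmp_path / "report")
        import json

        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["auroc"] == 1.0
        assert (tmp_path / "report.roc.tsv").exists()
        assert (tmp_path / "report.pr.tsv").exists()

    def test_plot_writes_figure(self, tmp_path):
        labels = np.repeat([0, 1], 50)
        report = ev.evaluate_scores(np.arange(100.0), labels)
        out = tmp_path / "curves.png"
        report.plot(out)
        assert out.stat().st_size > 0

    def test_dataset_descriptor(self, null_pipeline):
        report = null_pipeline["report"]
        n_pos = sum(1 for s in null_pipeline["test_set"] if s.label == "positive")
        assert report.n_pos == n_pos
        assert report.n_neg == 10 * n_pos
        assert report.ratio == pytest.approx(10.0)


class TestKFoldCV:
    def test_fold_structure_and_coverage(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, 5))
        from sklearn.model_selection import StratifiedKFold

        sizes = [len(te) for _, te in
                 StratifiedKFold(5, shuffle=True, random_state=0).split(X, y)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 80

    def test_zero_signal_oof_auroc_near_half(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 150)
        X = rng.normal(size=(300, 10))
        report = ev.kfold_cv(
            X, y, k=5, config=ev.CVConfig(mode="full", C=1.0, gamma=0.1), seed=0
        )
        assert 0.4 < report.auroc < 0.6

    def test_signal_recovered_out_of_fold(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 60)
        X = rng.normal(size=(120, 4))
        X[:, 0] += 3.0 * y
        report = ev.kfold_cv(
            X, y, k=5,
            config=ev.CVConfig(C=None, gamma=None, C_grid=(1.0, 8.0),
                               gamma_grid=(0.05, 0.5), grid_folds=3),
            seed=1,
        )
        assert report.auroc > 0.95
        assert len(report.extras["cv"]["hyperparameters_per_fold"]) == 5

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 3))
        cfg = ev.CVConfig(C=2.0, gamma=0.2)
        a = ev.kfold_cv(X, y, k=3, config=cfg, seed=4)
        b = ev.kfold_cv(X, y, k=3, config=cfg, seed=4)
        assert np.array_equal(a.roc_fpr, b.roc_fpr)
        assert a.auroc == b.auroc

    def test_k_exceeding_class_size_rejected(self):
        y = np.array([0, 0, 0, 1, 1])
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="smaller class"):
            ev.kfold_cv(X, y, k=3, config=ev.CVConfig(C=1.0, gamma=0.1))
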