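"""Scaler, grid search, SVM training, calibration, persistence."""

import numpy as np
import pytest

from m6asite import classifier as clf
from m6asite.features import feature_dim
from m6asite.sequences import Transcript


def _toy_matrix(mode: str, y: np.ndarray, shift: float, seed: int = 0):
    """Feature-shaped random matrix whose first column carries the labels."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(len(y), feature_dim(mode)))
    X[:, 0] += shift * y
    return X


class TestScaler:
    def test_standardizes_training_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(loc=3.0, scale=2.0, size=(50, 4))
        scaler = clf.fit_scaler(X)
        Z = clf.apply_scaler(scaler, X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_passes_through(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        scaler = clf.fit_scaler(X)
        Z = clf.apply_scaler(scaler, X)
        assert np.array_equal(Z[:, 0], X[:, 0])

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        X[:, 2] = 7.0  # constant column
        scaler = clf.fit_scaler(X)
        assert np.allclose(clf.invert_scaler(scaler, clf.apply_scaler(scaler, X)), X)

    def test_dimension_mismatch(self):
        scaler = clf.fit_scaler(np.ones((5, 3)) * np.arange(3))
        with pytest.raises(ValueError, match="dimension"):
            clf.apply_scaler(scaler, np.ones((2, 4)))


class TestGridSearch:
    @pytest.fixture()
    def separable_2d(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 2)) + 8.0 * y[:, None]
        return X, y

    def test_single_cell_grid(self, separable_2d):
        X, y = separable_2d
        assert clf.grid_search(X, y, C_grid=[2.0], gamma_grid=[0.5], k_folds=3) \
            == (2.0, 0.5)

    def test_tie_break_prefers_smallest_c_then_gamma(self, separable_2d):
        # every cell reaches AUROC 1.0 on linearly separable data
        X, y = separable_2d
        C_grid, gamma_grid = [1.0, 4.0], [0.125, 0.5]
        for C in C_grid:
            for gamma in gamma_grid:
                assert clf.grid_search(X, y, [C], [gamma], k_folds=3) == (C, gamma)
        assert clf.grid_search(X, y, C_grid, gamma_grid, k_folds=3) == (1.0, 0.125)

    def test_deterministic_given_seed(self, separable_2d):
        X, y = separable_2d
        a = clf.grid_search(X, y, [0.5, 2], [0.1, 1], k_folds=3, seed=5)
        b = clf.grid_search(X, y, [0.5, 2], [0.1, 1], k_folds=3, seed=5)
        assert a == b

    def test_empty_grid_rejected(self, separable_2d):
        X, y = separable_2d
        with pytest.raises(ValueError):
            clf.grid_search(X, y, [], [0.1])


class TestTrain:
    def test_single_class_rejected(self):
        X = _toy_matrix("full", np.zeros(10, dtype=int), 0.0)
        with pytest.raises(ValueError, match="single class"):
            clf.train(X, np.zeros(10), "full", C=1.0, gamma=0.01)

    def test_wrong_dimension_rejected(self):
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="columns"):
            clf.train(np.ones((10, 3)), y, "mature", C=1.0, gamma=0.01)

    def test_retraining_reproduces_scores(self):
        y = np.repeat([0, 1], 25)
        X = _toy_matrix("full", y, 2.0)
        probe = _toy_matrix("full", y, 2.0, seed=9)
        s1 = clf.train(X, y, "full", C=4.0, gamma=0.002).score(probe)
        s2 = clf.train(X, y, "full", C=4.0, gamma=0.002).score(probe)
        assert np.array_equal(s1, s2)

    def test_row_permutation_invariance(self):
        y = np.repeat([0, 1], 25)
        X = _toy_matrix("full", y, 2.0)
        probe = _toy_matrix("full", y, 2.0, seed=9)
        perm = np.random.default_rng(3).permutation(len(y))
        s1 = clf.train(X, y, "full", C=4.0, gamma=0.002).score(probe)
        s2 = clf.train(X[perm], y[perm], "full", C=4.0, gamma=0.002).score(probe)
        assert np.allclose(s1, s2, atol=1e-6)

    def test_scores_finite_and_oriented(self):
        y = np.repeat([0, 1], 25)
        X = _toy_matrix("full", y, 3.0)
        predictor = clf.train(X, y, "full", C=4.0, gamma=0.002)
        s = predictor.score(X)
        assert np.all(np.isfinite(s))
        assert s[y == 1].mean() > s[y == 0].mean()


class TestCalibration:
    def _predictor_with_scores(self, scores):
        """Wrap fixed scores in the calibration interface."""

        class Fake:
            mode = "mature"
            thresholds = None

            def score(self, X):
                return np.asarray(X)[:, 0]

        fake = Fake()
        X = np.array(scores, dtype=float)[:, None]
        return fake, X

    def test_order_statistics_example(self):
        fake, X = self._predictor_with_scores(np.arange(1, 101))
        y = np.zeros(100, dtype=int)
        y[:1] = 0  # all negatives
        # need one positive for labels; append it
        X = np.vstack([X, [[1000.0]]])
        y = np.append(y, 1)
        table = clf.calibrate_thresholds(fake, X, y, targets={"high": 0.90,
                                                              "moderate": 0.85,
                                                              "low": 0.80})
        assert table.threshold("high") == 91.0
        assert table.entries["high"].achieved_specificity >= 0.90

    def test_full_specificity_exceeds_max_negative(self):
        neg = np.arange(1, 101, dtype=float)
        thr = clf.threshold_for_specificity(neg, 1.0)
        assert thr > 100.0

    def test_achieved_specificity_monotone_in_target(self):
        rng = np.random.default_rng(4)
        neg = rng.normal(size=500)
        achieved = []
        for target in [0.5, 0.8, 0.9, 0.95, 1.0]:
            thr = clf.threshold_for_specificity(neg, target)
            achieved.append(np.mean(neg < thr))
        assert all(b >= a for a, b in zip(achieved, achieved[1:]))

    def test_no_negatives_rejected(self):
        fake, X = self._predictor_with_scores([1.0, 2.0])
        with pytest.raises(ValueError, match="no negatives"):
            clf.calibrate_thresholds(fake, X, np.ones(2, dtype=int))

    def test_threshold_table_requires_decreasing_specificity(self):
        with pytest.raises(ValueError, match="decrease"):
            clf.ThresholdTable(
                {
                    "high": clf.ThresholdEntry(2.0, 0.8, 0.80),
                    "moderate": clf.ThresholdEntry(1.0, 0.9, 0.90),
                }
            )


class TestPredictSites:
    def test_no_drach_gives_empty(self, null_pipeline):
        predictor = null_pipeline["predictor"]
        t = Transcript("bare", "GGGGGGGGGG", mode="full")
        assert clf.predict_sites(predictor, [t]) == []

    def test_threshold_nesting(self, null_pipeline):
        predictor = null_pipeline["predictor"]
        t = null_pipeline["transcripts"][0]
        preds = clf.predict_sites(predictor, [t])
        assert preds, "expected candidates on a 1.2-kb transcript"
        for p in preds:
            assert p.site.motif[2] == "A"
            if p.passes["high"]:
                assert p.passes["moderate"]
            if p.passes["moderate"]:
                assert p.passes["low"]

    def test_mode_mismatch_rejected(self, null_pipeline):
        predictor = null_pipeline["predictor"]  # full mode
        t = Transcript("x", "GGACT" * 30, mode="mature")
        with pytest.raises(ValueError, match="mode"):
            clf.predict_sites(predictor, [t])


class TestPersistence:
    def test_roundtrip_scores_identical(self, tmp_path, null_pipeline):
        predictor = null_pipeline["predictor"]
        probe = null_pipeline["X_test"][:25]
        path = tmp_path / "model.joblib"
        clf.save_model(predictor, path)
        loaded = clf.load_model(path)
        assert np.array_equal(loaded.score(probe), predictor.score(probe))
        assert loaded.mode == predictor.mode
        assert loaded.thresholds.to_dict() == predictor.thresholds.to_dict()

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            clf.load_model(tmp_path / "nope.joblib")

    def test_corrupted_file(self, tmp_path):
        p = tmp_path / "junk.joblib"
        p.write_text("this is not a model")
        with pytest.raises(clf.ModelFormatError):
            clf.load_model(p)

    def test_version_mismatch(self, tmp_path, null_pipeline):
        import joblib

        path = tmp_path / "model.joblib"
        clf.save_model(null_pipeline["predictor"], path)
        payload = joblib.load(path)
        payload["version"] = 99
        joblib.dump(payload, path)
        with pytest.raises(clf.ModelFormatError, match="version"):
            clf.load_model(path)
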