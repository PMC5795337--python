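"""Calibration/prediction split, PLS-DA, RBFNN, SVM, and evaluation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from libsid import models as M
from libsid.core import ShotMeta, SpectrumSet


def _labelled_set(counts: dict[int, int], n_points: int = 4, samples_per_variety: int = 2):
    rng = np.random.default_rng(0)
    grid = np.linspace(300.0, 303.0, n_points)
    rows, meta = [], []
    for v, n in counts.items():
        for i in range(n):
            rows.append(rng.normal(size=n_points) + v)
            meta.append(ShotMeta(v, f"V{v}S{i % samples_per_variety:02d}", f"T{i:02d}"))
    return SpectrumSet(grid, np.array(rows), meta)


def _blobs(n_per_class=12, dim=20, sep=8.0, seed=0, center_seed=42):
    rng = np.random.default_rng(seed)
    centers = np.random.default_rng(center_seed).normal(0.0, 1.0, (4, dim))
    centers *= sep / np.linalg.norm(centers, axis=1, keepdims=True)
    X, y = [], []
    for c in range(4):
        X.append(centers[c] + rng.normal(0.0, 0.3, (n_per_class, dim)))
        y.extend([c + 1] * n_per_class)
    return np.vstack(X), np.array(y)


class TestSplit:
    def test_two_to_one_counts(self):
        sset = _labelled_set({v: 288 for v in (1, 2, 3, 4)})
        cal, pred = M.split_calibration_prediction(sset, M.SplitConfig(seed=3))
        assert cal.n_shots == 768 and pred.n_shots == 384
        for v in (1, 2, 3, 4):
            assert (cal.varieties == v).sum() == 192

    def test_disjoint_exhaustive_and_deterministic(self):
        sset = _labelled_set({1: 9, 2: 9, 3: 9, 4: 9})
        i1, p1 = M.split_indices(sset, M.SplitConfig(seed=7))
        i2, p2 = M.split_indices(sset, M.SplitConfig(seed=7))
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(p1, p2)
        assert not set(i1) & set(p1)
        assert len(i1) + len(p1) == 36

    def test_extreme_ratio_clamped(self):
        sset = _labelled_set({1: 3, 2: 3, 3: 3, 4: 3})
        cal, pred = M.split_calibration_prediction(sset, M.SplitConfig(calibration_ratio=0.999))
        assert cal.n_shots == 8 and pred.n_shots == 4  # 2/1 per variety

    def test_sample_unit_keeps_samples_together(self):
        sset = _labelled_set({v: 12 for v in (1, 2, 3, 4)}, samples_per_variety=4)
        cal, pred = M.split_calibration_prediction(
            sset, M.SplitConfig(unit="sample", seed=0)
        )
        cal_samples = {m.sample_id for m in cal.meta}
        pred_samples = {m.sample_id for m in pred.meta}
        assert not cal_samples & pred_samples

    def test_too_few_shots_errors(self):
        sset = _labelled_set({1: 2, 2: 5, 3: 5, 4: 5})
        with pytest.raises(ValueError, match="variety 1"):
            M.split_indices(sset, M.SplitConfig())


class TestPLSDA:
    def test_perfectly_linear_needs_one_lv(self, rng):
        y = np.repeat([1, 2, 3, 4], 10)
        X = 0.05 * rng.normal(size=(40, 3))
        X[:, 0] = y.astype(float)
        model = M.train_plsda(X, y, M.PLSDAConfig(max_lv=3))
        assert model.hyperparameters["n_lv"] == 1
        assert model.hyperparameters["loo_accuracy"] == 100.0
        np.testing.assert_array_equal(M.predict_plsda(model, X), y)

    def test_chosen_lv_capped_with_warning(self, rng):
        y = np.repeat([1, 2, 3, 4], 3)
        X = rng.normal(size=(12, 3))
        with pytest.warns(RuntimeWarning, match="capped"):
            model = M.train_plsda(X, y, M.PLSDAConfig(max_lv=20))
        assert model.hyperparameters["n_lv"] <= 3

    @pytest.mark.parametrize(
        "score,expected",
        [(2.4, 2), (2.6, 3), (7.0, 4), (-1.0, 1), (2.5, 2), (3.5, 3), (1.0, 1)],
    )
    def test_threshold_mapping(self, score, expected):
        classes = np.array([1, 2, 3, 4])
        assert M._classify_integer(np.array(score), classes) == expected

    @given(st.floats(min_value=-2.0, max_value=8.0), st.floats(min_value=0.0, max_value=2.0))
    def test_threshold_mapping_monotone(self, score, delta):
        classes = np.array([1, 2, 3, 4])
        lo = M._classify_integer(np.array(score), classes)
        hi = M._classify_integer(np.array(score + delta), classes)
        assert hi >= lo

    def test_one_hot_coding(self, rng):
        X, y = _blobs(n_per_class=8, dim=5, sep=6.0)
        model = M.train_plsda(X, y, M.PLSDAConfig(max_lv=4, class_coding="one_hot"))
        assert (M.predict_plsda(model, X) == y).mean() == 1.0


class TestRBFNN:
    def test_interpolation_limit_reproduces_training_labels(self, rng):
        X, y = _blobs(n_per_class=3, dim=4, sep=5.0)
        cfg = M.RBFNNConfig(spread_grid=(0.05,), ridge=1e-12, selection="calibration")
        model = M.train_rbfnn(X, y, cfg)
        np.testing.assert_array_equal(M.predict_rbfnn(model, X), y)

    def test_nearest_center_in_small_spread_limit(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]])
        y = np.array([1, 1, 2, 2])
        cfg = M.RBFNNConfig(spread_grid=(0.2,), selection="calibration")
        model = M.train_rbfnn(X, y, cfg)
        got = M.predict_rbfnn(model, np.array([[0.05, 0.01], [5.05, 4.9]]))
        np.testing.assert_array_equal(got, [1, 2])

    def test_chosen_spread_on_grid_and_cv_selection(self):
        X, y = _blobs(n_per_class=10, dim=6, sep=6.0, seed=2)
        grid = (0.5, 1.0, 2.0, 4.0)
        model = M.train_rbfnn(X, y, M.RBFNNConfig(spread_grid=grid, cv_folds=3))
        assert model.hyperparameters["spread"] in grid
        assert (M.predict_rbfnn(model, X) == y).mean() == 1.0

    def test_needs_two_per_class(self):
        with pytest.raises(ValueError, match="2 calibration rows"):
            M.train_rbfnn(np.eye(3), np.array([1, 2, 3]), M.RBFNNConfig(spread_grid=(1.0,)))


class TestSVM:
    def test_separable_toy_perfect_calibration(self):
        X = np.vstack([np.full((5, 2), -2.0), np.full((5, 2), 2.0)])
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        y = np.array([1] * 5 + [2] * 5)
        model = M.train_svm(X, y, M.SVMConfig(grid_step_log2=4.0, cv_folds=2))
        assert (M.predict_svm(model, X) == y).mean() == 1.0

    def test_tuned_parameters_inside_declared_range(self):
        X, y = _blobs(n_per_class=6, dim=5, sep=5.0, seed=1)
        model = M.train_svm(X, y, M.SVMConfig(grid_step_log2=2.0, cv_folds=3))
        assert 2.0**-8 <= model.hyperparameters["C"] <= 2.0**8
        assert 2.0**-8 <= model.hyperparameters["gamma"] <= 2.0**8

    def test_duplicating_a_training_point_keeps_decision(self):
        X, y = _blobs(n_per_class=6, dim=3, sep=6.0, seed=3)
        cfg = M.SVMConfig(log2_C_range=(2.0, 2.0), log2_gamma_range=(-2.0, -2.0),
                          grid_step_log2=1.0, selection="calibration")
        probe = np.random.default_rng(4).normal(0.0, 3.0, (30, 3))
        base = M.predict_svm(M.train_svm(X, y, cfg), probe)
        X2 = np.vstack([X, X[0]])
        y2 = np.append(y, y[0])
        dup = M.predict_svm(M.train_svm(X2, y2, cfg), probe)
        np.testing.assert_array_equal(base, dup)


class TestEvaluateAndBlobs:
    def test_all_three_classifiers_solve_separated_blobs(self):
        X, y = _blobs(n_per_class=12, dim=20, sep=10.0, seed=5)
        Xp, yp = _blobs(n_per_class=6, dim=20, sep=10.0, seed=6)
        trained = [
            M.train_plsda(X, y, M.PLSDAConfig(max_lv=5)),
            M.train_rbfnn(X, y, M.RBFNNConfig(spread_grid=(1.0, 4.0, 16.0), cv_folds=3)),
            M.train_svm(X, y, M.SVMConfig(grid_step_log2=4.0, cv_folds=3)),
        ]
        for model in trained:
            report = M.evaluate(model, (X, y), (Xp, yp))
            assert report.total_calibration == 100.0
            assert report.total_prediction == 100.0

    def test_constant_predictor_accuracies(self):
        model = M.TrainedModel(
            kind="plsda",
            hyperparameters={},
            fit_state={
                "x_mean": np.zeros(2),
                "y_mean": np.array([1.0]),
                "coef": np.zeros((2, 1)),
                "coding": "integer",
                "threshold": 0.5,
            },
            training_class_labels=[1, 2, 3, 4],
        )
        X = np.zeros((8, 2))
        y = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        report = M.evaluate(model, (X, y), (X, y))
        assert report.total_calibration == 25.0
        np.testing.assert_array_equal(report.per_class_calibration, [100.0, 0.0, 0.0, 0.0])
        # total equals the sample-weighted per-class mean on balanced data
        assert report.total_calibration == pytest.approx(report.per_class_calibration.mean())

    def test_unknown_label_warns_and_counts_as_error(self):
        X, y = _blobs(n_per_class=6, dim=4, sep=8.0, seed=7)
        model = M.train_rbfnn(X, y, M.RBFNNConfig(spread_grid=(2.0,), selection="calibration"))
        y_bad = y.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            M.evaluate(model, (X, y), (X, y))  # no warning when labels known
        # labels outside 1..4 are rejected by ShotMeta but evaluate sees raw
        # arrays; present a prediction set with a label unseen in training
        X2, y2 = X[:4], np.array([1, 2, 3, 3])
        model2 = M.train_rbfnn(
            np.vstack([X2, X2]), np.concatenate([y2, y2]),
            M.RBFNNConfig(spread_grid=(2.0,), selection="calibration"),
        )
        with pytest.warns(RuntimeWarning, match="absent from training"):
            M.evaluate(model2, (X2, y2), (X[:2], np.array([4, 4])))


class TestModelSerialization:
    def test_json_round_trip_predictions(self, tmp_path):
        from libsid.serialize import load_model, save_model

        X, y = _blobs(n_per_class=6, dim=5, sep=6.0, seed=8)
        probe = np.random.default_rng(9).normal(0.0, 3.0, (20, 5))
        trained = [
            M.train_plsda(X, y, M.PLSDAConfig(max_lv=3)),
            M.train_rbfnn(X, y, M.RBFNNConfig(spread_grid=(1.0, 4.0), selection="calibration")),
            M.train_svm(X, y, M.SVMConfig(grid_step_log2=8.0, selection="calibration")),
        ]
        for model in trained:
            path = tmp_path / f"{model.kind}.json"
            save_model(model, path)
            back = load_model(path)
            np.testing.assert_array_equal(M.predict(back, probe), M.predict(model, probe))
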