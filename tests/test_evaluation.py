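import numpy as np
import pytest

from eegscreen.evaluation import (
    CLASSICAL_MODELS,
    EvalReport,
    ModelSpec,
    StratificationError,
    benchmark_suite,
    build_model,
    compute_metrics,
    run_cv,
)
from eegscreen._nn import MLPNet
from tests.conftest import gaussian_feature_matrix


class TestModelSpec:
    def test_dnn_defaults(self):
        spec = ModelSpec(kind="dnn")
        assert spec.hidden_sizes == (256, 128, 64, 32)
        assert spec.batch_size == 16
        assert spec.optimizer == "nadam"
        assert spec.learning_rate == pytest.approx(1e-3)
        assert spec.max_epochs == 30
        assert spec.dropout == 0.5

    def test_snn_has_three_blocks_dnn_four(self):
        assert len(ModelSpec(kind="snn").hidden_sizes) == 3
        assert len(ModelSpec(kind="dnn").hidden_sizes) == 4
        with pytest.raises(ValueError, match="4 hidden"):
            ModelSpec(kind="dnn", hidden_sizes=(10, 10))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="dnn", dropout=1.0)
        with pytest.raises(ValueError):
            ModelSpec(kind="dnn", learning_rate=0.0)


class TestBuildModel:
    def test_dnn_accepts_topk_input(self):
        model = build_model(ModelSpec(kind="dnn", seed=0), input_dim=20)
        proba = model.predict_proba(np.zeros((3, 20)))
        assert proba.shape == (3, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_same_seed_same_initialization(self):
        a = build_model(ModelSpec(kind="dnn", seed=5), input_dim=10)
        b = build_model(ModelSpec(kind="dnn", seed=5), input_dim=10)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    @pytest.mark.parametrize("name", ["fine_tree", "lda", "linear_svm",
                                      "fine_knn", "ensemble_bagged_trees"])
    def test_classical_registry(self, name):
        model = build_model(ModelSpec(kind=f"classical:{name}"), input_dim=8)
        assert hasattr(model, "fit")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelSpec(kind="classical:nope"), input_dim=4)
        with pytest.raises(ValueError):
            build_model(ModelSpec(kind="transformer"), input_dim=4)

    def test_registry_is_complete(self):
        for name in CLASSICAL_MODELS:
            build_model(ModelSpec(kind=f"classical:{name}"), input_dim=8)


class TestComputeMetrics:
    def test_printed_confusion_example(self):
        # TP=83 TN=89 FP=0 FN=2 -> ~98.9% acc, ~97.6% sens, 100% spec
        m = compute_metrics({"TP": 83, "TN": 89, "FP": 0, "FN": 2})
        assert round(100 * m["accuracy"], 1) == 98.9
        assert round(100 * m["sensitivity"], 1) == 97.6
        assert m["specificity"] == pytest.approx(1.0)

    def test_perfect_predictions(self):
        y = np.repeat([0, 1], 10)
        scores = y.astype(float)
        m = compute_metrics({"TP": 10, "TN": 10, "FP": 0, "FN": 0},
                            y_true=y, scores=scores)
        for name in ("accuracy", "precision", "recall", "f1",
                     "sensitivity", "specificity"):
            assert m[name] == pytest.approx(1.0)
        assert m["auc"] == pytest.approx(1.0)

    def test_constant_scores_auc_half(self):
        y = np.repeat([0, 1], 8)
        m = compute_metrics({"TP": 4, "TN": 4, "FP": 4, "FN": 4},
                            y_true=y, scores=np.zeros(16))
        assert m["auc"] == pytest.approx(0.5)

    def test_weighted_recall_equals_accuracy(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0 or tp + fn == 0 or tn + fp == 0:
                continue
            m = compute_metrics({"TP": int(tp), "TN": int(tn),
                                 "FP": int(fp), "FN": int(fn)})
            assert m["recall"] == pytest.approx(m["accuracy"])

    def test_undefined_metric_flagged_not_zeroed(self):
        m = compute_metrics({"TP": 0, "TN": 5, "FP": 0, "FN": 0})
        assert m["sensitivity"] is None
        assert "sensitivity" in m["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics({"TP": -1, "TN": 1, "FP": 0, "FN": 0})


class TestRunCv:
    def test_every_sample_tested_once_and_stratified(self, separable_features):
        fm = separable_features
        spec = ModelSpec(kind="classical:lda")
        report = run_cv(fm, spec, n_folds=5, seed=0)
        sizes = [sum(c.values()) for c in report.confusions]
        assert sum(sizes) == fm.n_epochs
        assert max(sizes) - min(sizes) <= 1
        # fold class proportions within one sample of global proportion
        global_pos = fm.labels.mean()
        for c in report.confusions:
            n = sum(c.values())
            pos = c["TP"] + c["FN"]
            assert abs(pos - global_pos * n) <= 1

    def test_separable_dnn_high_accuracy(self, separable_features):
        # dropout 0.5 on very narrow layers underfits; keep moderate widths
        spec = ModelSpec(kind="dnn", hidden_sizes=(64, 32, 16, 8),
                         max_epochs=30, seed=0)
        # margin oracle: classes must be linearly separated along the mean of
        # the informative columns before we demand the model learn them
        X, y = separable_features.values, separable_features.labels
        proj = X[:, :4].mean(axis=1)
        margin = proj[y == 1].min() - proj[y == 0].max()
        assert margin > 0
        report = run_cv(separable_features, spec, n_folds=5, seed=0)
        assert report.aggregate["average"]["accuracy"] >= 0.95

    def test_deterministic_given_seed(self, separable_features):
        spec = ModelSpec(kind="snn", hidden_sizes=(16, 8, 8), max_epochs=5,
                         seed=2)
        r1 = run_cv(separable_features, spec, n_folds=4, seed=3)
        r2 = run_cv(separable_features, spec, n_folds=4, seed=3)
        assert r1.confusions == r2.confusions
        assert r1.aggregate == r2.aggregate

    def test_small_class_rejected(self):
        fm = gaussian_feature_matrix(n_per_class=4)
        with pytest.raises(ValueError, match="n_folds"):
            run_cv(fm, ModelSpec(kind="classical:lda"), n_folds=10)

    def test_grouped_mode_runs(self, small_feature_matrix):
        spec = ModelSpec(kind="classical:lda")
        report = run_cv(small_feature_matrix, spec, n_folds=2, seed=0,
                        grouped=True)
        assert report.n_folds == 2

    def test_weighted_recall_equals_accuracy_per_fold(self, separable_features):
        report = run_cv(separable_features, ModelSpec(kind="classical:lda"),
                        n_folds=5, seed=1)
        for fold in report.per_fold:
            assert fold["recall"] == pytest.approx(fold["accuracy"])


class TestBenchmarkSuite:
    def test_table_layout_and_determinism(self, separable_features):
        settings = {"combined": separable_features,
                    "top4": separable_features.select(range(4))}
        specs = [ModelSpec(kind="classical:lda"),
                 ModelSpec(kind="classical:fine_tree")]
        t1 = benchmark_suite(settings, specs, n_folds=4, seed=0)
        t2 = benchmark_suite(settings, specs, n_folds=4, seed=0)
        assert len(t1) == 4
        assert set(t1.columns) >= {"feature_set", "model", "n_features",
                                   "avg_accuracy", "max_accuracy"}
        assert t1.equals(t2)


class TestMLPNet:
    def test_overfits_tiny_problem(self, rng):
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] *= 4  # widen margin
        net = MLPNet(6, (16, 8), dropout=0.2, max_epochs=40, seed=0)
        net.fit(X, y)
        assert (net.predict(X) == y).mean() >= 0.9

    def test_predict_proba_rows_sum_to_one(self, rng):
        net = MLPNet(5, (8, 8), seed=0)
        proba = net.predict_proba(rng.normal(size=(10, 5)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert np.all(proba >= 0)

    def test_early_stopping_restores_best(self, rng):
        X = rng.normal(size=(120, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=120) > 0).astype(int)
        net = MLPNet(4, (8, 8), max_epochs=50, patience=3, seed=1)
        net.fit(X[:90], y[:90], X[90:], y[90:])
        # training must have stopped with finite parameters
        assert all(np.isfinite(v).all() for v in net.params.values())
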