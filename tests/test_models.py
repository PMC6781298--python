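"""Classifier suite: architectures, the train/predict contract, determinism."""

import numpy as np
import pytest

from dresnap.models import (
    ModelConfig,
    build_cnn,
    build_dnn,
    build_model,
    predict_scores,
    train,
)
from dresnap.models.nn import Conv1D, Dense, Dropout, FullHeightConv, PReLU
from dresnap.simulate import make_snapshot_examples


@pytest.fixture(scope="module")
def small_separable():
    """200 separable snapshot examples (fast to fit)."""
    return make_snapshot_examples(100, 100, seed=42)


class TestDnnArchitecture:
    def test_hidden_layer_widths(self):
        net = build_dnn(ModelConfig(kind="dnn"))
        widths = [l.W.shape[1] for l in net.layer_of_type(Dense)]
        assert widths == [600, 500, 400, 1]
        assert net.layer_of_type(Dense)[0].W.shape[0] == 480

    def test_dropout_rates(self):
        net = build_dnn(ModelConfig(kind="dnn"))
        assert [d.rate for d in net.layer_of_type(Dropout)] == [0.3, 0.3, 0.3]

    def test_single_finite_scalar_output(self):
        net = build_dnn(ModelConfig(kind="dnn"))
        out = net.predict(np.random.default_rng(0).random((3, 480)))
        assert out.shape == (3,) and np.all(np.isfinite(out))


class TestCnnArchitecture:
    def test_conv_and_pool_shapes_by_introspection(self):
        net = build_cnn(ModelConfig(kind="cnn"))
        shapes = net.activation_shapes(np.zeros((1, 24, 20)))
        assert shapes[0] == (1, 64, 19)   # full-height 24x2 kernels, stride 1
        assert shapes[2] == (1, 64, 18)   # second conv, 1x2 kernels
        assert shapes[4] == (1, 64, 9)    # max-pool 1x2
        assert shapes[-1] == (1, 1)

    def test_dropout_rates(self):
        net = build_cnn(ModelConfig(kind="cnn"))
        assert [d.rate for d in net.layer_of_type(Dropout)] == [0.5, 0.5, 0.3]

    def test_kernel_counts(self):
        net = build_cnn(ModelConfig(kind="cnn"))
        conv1 = net.layer_of_type(FullHeightConv)[0]
        conv2 = net.layer_of_type(Conv1D)[0]
        assert conv1.W.shape == (64, 48)    # 64 kernels spanning 24 marks x 2 bins
        assert conv2.W.shape == (64, 128)   # 64 kernels over 64 channels x 2

    def test_wrong_input_shape_rejected(self):
        net = build_cnn(ModelConfig(kind="cnn"))
        with pytest.raises(ValueError):
            net.predict(np.zeros((2, 23, 20)))

    def test_prelu_slope_initialised_quarter(self):
        net = build_cnn(ModelConfig(kind="cnn"))
        assert all(p.a[0] == 0.25 for p in net.layer_of_type(PReLU))


class TestClassicalModels:
    def test_linear_svm_separates_separable_toy(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-3, 0.3, (50, 2)), rng.normal(3, 0.3, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        config = ModelConfig(kind="linear_svm")
        model = build_model(config)
        model.fit(x, y)
        assert model.score(x, y) == 1.0

    def test_random_forest_vote_fraction_near_one_on_repeated_point(self):
        x = np.vstack([np.zeros((90, 3)), np.ones((10, 3))])
        y = np.array([1] * 90 + [0] * 10)
        config = ModelConfig(kind="random_forest", seed=0)
        from dresnap.models.suite import TrainedModel
        model = build_model(config)
        model.fit(x, y)
        tm = TrainedModel(config=config, estimator=model, input_shape=(3,))
        assert tm.scores(np.zeros((1, 3)))[0] > 0.9

    def test_kernel_svm_score_orders_points_near_boundary(self):
        """Score grows with distance from the boundary (within the margin
        region; RBF scores decay again far past the support vectors)."""
        x = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (x.ravel() > 0).astype(int)
        config = ModelConfig(kind="kernel_svm")
        model = build_model(config)
        model.fit(x, y)
        probes = np.linspace(0.05, 0.6, 8).reshape(-1, 1)
        scores = model.decision_function(probes)
        assert np.all(np.diff(scores) > 0)
        assert np.all(model.decision_function(-probes) < 0)


class TestTrainPredictContract:
    @pytest.mark.parametrize("kind", ["linear_svm", "kernel_svm", "random_forest"])
    def test_same_contract_classical(self, kind, small_separable):
        config = ModelConfig(kind=kind, seed=0)
        tm = train(build_model(config), small_separable, config)
        scores = predict_scores(tm, small_separable)
        assert len(scores) == len(small_separable)
        assert np.all(np.isfinite(scores.scores))

    @pytest.mark.parametrize("kind", ["dnn", "cnn"])
    def test_same_contract_neural(self, kind, small_separable):
        config = ModelConfig(kind=kind, seed=0, epochs=3)
        tm = train(build_model(config), small_separable, config)
        scores = predict_scores(tm, small_separable)
        assert len(scores) == len(small_separable)
        assert np.all(np.isfinite(scores.scores))

    def test_empty_prediction_list(self, small_separable):
        config = ModelConfig(kind="linear_svm", seed=0)
        tm = train(build_model(config), small_separable, config)
        assert len(predict_scores(tm, [])) == 0

    def test_duplicate_examples_score_identically(self, small_separable):
        config = ModelConfig(kind="dnn", seed=0, epochs=2)
        tm = train(build_model(config), small_separable, config)
        s = predict_scores(tm, [small_separable[0], small_separable[0]]).scores
        assert s[0] == s[1]

    def test_single_class_rejected_for_margin_models(self, small_separable):
        positives = [e for e in small_separable if e.label == 1]
        config = ModelConfig(kind="linear_svm", seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(build_model(config), positives, config)

    def test_default_epochs_is_fifty(self):
        assert ModelConfig(kind="dnn").epochs == 50


class TestTrainingDynamics:
    def test_same_seed_identical_predictions(self, small_separable):
        probe = make_snapshot_examples(10, 10, seed=99)
        runs = []
        for _ in range(2):
            config = ModelConfig(kind="dnn", seed=5, epochs=3)
            tm = train(build_model(config), small_separable, config)
            runs.append(predict_scores(tm, probe).scores)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_loss_decreases_on_separable_data(self, small_separable):
        config = ModelConfig(kind="dnn", seed=0, epochs=15)
        tm = train(build_model(config), small_separable, config)
        hist = tm.estimator.loss_history
        assert len(hist) == 15
        # smoothed check: late-training loss well below early-training loss
        assert np.mean(hist[-3:]) < np.mean(hist[:3])
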