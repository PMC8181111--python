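import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgfusion.gru import (GruParams, TrainConfig, _backward, cross_entropy,
                           gru_cell, gru_predict, init_params, load_params,
                           loss, save_params, softmax, train_gru)


def scalar_params(w=1.0):
    return GruParams(Wz=np.array([[w, w]]), Wr=np.array([[w, w]]),
                     Wh=np.array([[w, w]]), bz=np.zeros(1), br=np.zeros(1),
                     bh=np.zeros(1), W1=np.eye(1), b1=np.zeros(1),
                     W2=np.eye(1), b2=np.zeros(1))


class TestGruCell:
    def test_closed_update_gate_keeps_state(self):
        p = scalar_params()
        p.bz[:] = -50.0  # force z ~ 0
        h = gru_cell(np.array([0.7]), np.array([0.4]), p)
        assert h[0] == pytest.approx(0.4, abs=1e-12)

    def test_zero_weights_halve_previous_state(self):
        p = scalar_params(0.0)
        v = 0.8
        h = gru_cell(np.array([0.0]), np.array([v]), p)
        # z = sigmoid(0) = 0.5, candidate = tanh(0) = 0 -> h = 0.5 v
        assert h[0] == pytest.approx(0.5 * v)

    def test_hand_computed_scalar_example(self):
        p = scalar_params(1.0)
        h = gru_cell(np.array([1.0]), np.array([0.0]), p)
        sig = 1.0 / (1.0 + np.exp(-1.0))
        expected = sig * np.tanh(1.0)  # ~0.7311 * 0.7616 ~ 0.5568
        assert h[0] == pytest.approx(expected, abs=1e-9)
        assert h[0] == pytest.approx(0.5568, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        p = scalar_params()
        with pytest.raises(ValueError):
            gru_cell(np.array([1.0, 2.0]), np.array([0.0]), p)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_hidden_state_stays_bounded(self, seed):
        """h_t is a convex mix of h_prev and tanh output: stays in [-1, 1]."""
        rng = np.random.default_rng(seed)
        p = init_params(cell=4, fc_size=3, input_size=2, seed=seed, scale=2.0)
        h = rng.uniform(-1, 1, size=4)
        for _ in range(20):
            h = gru_cell(rng.standard_normal(2), h, p)
            assert np.all(np.abs(h) <= 1.0 + 1e-12)


class TestSoftmaxAndLoss:
    def test_uniform_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(4)), 0.25)

    def test_shift_invariance(self):
        v = np.array([0.3, -1.2, 4.0, 0.0])
        np.testing.assert_allclose(softmax(v), softmax(v + 123.4), rtol=1e-12)

    def test_three_way_example(self):
        np.testing.assert_allclose(softmax(np.array([1.0, 2.0, 3.0])),
                                   [0.0900, 0.2447, 0.6652], atol=5e-5)

    def test_uniform_cross_entropy_is_log4(self):
        assert cross_entropy(np.zeros((1, 4)), [0]) == pytest.approx(np.log(4))

    def test_confident_correct_limit(self):
        logits = np.array([[100.0, 0.0, 0.0, 0.0]])
        assert cross_entropy(logits, [0]) == pytest.approx(0.0, abs=1e-30)

    def test_l2_term_direct_value(self):
        p = scalar_params(0.0)
        p.W1[:] = 1.0
        p.W2[:] = 2.0
        cfg = TrainConfig(l2_lambda=0.1, epochs=1)
        # weights {1, 2}: (0.1 / 2) * (1 + 4) = 0.25
        base = cross_entropy(np.zeros((1, 1)), [0])
        assert loss(np.zeros((1, 1)), [0], p, cfg, n=1) == \
            pytest.approx(base + 0.25)

    def test_regularized_loss_strictly_larger(self):
        p = init_params(cell=3, fc_size=2, input_size=1, seed=0)
        logits = np.array([[0.5, -0.2, 0.1, 0.0]])
        cfg0 = TrainConfig(l2_lambda=0.0, epochs=1)
        cfg1 = TrainConfig(l2_lambda=0.1, epochs=1)
        assert loss(logits, [1], p, cfg1) > loss(logits, [1], p, cfg0)

    def test_lambda_range_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig(l2_lambda=0.2)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        cfg = TrainConfig(cell=5, fc_size=4, frame_size=5, batch_size=8,
                          epochs=1, l2_lambda=0.05)
        params = init_params(cell=5, fc_size=4, input_size=5, n_classes=4,
                             seed=1, scale=0.3)
        X = rng.standard_normal((6, 20))
        y = rng.integers(0, 4, size=6)
        _cost, grads = _backward(params, X, y, cfg)
        eps = 1e-6
        for name, arr in params.all_arrays().items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                cp, _ = _backward(params, X, y, cfg)
                arr[i] = old - eps
                cm, _ = _backward(params, X, y, cfg)
                arr[i] = old
                num[i] = (cp - cm) / (2 * eps)
            scale = max(np.abs(num).max(), np.abs(grads[name]).max(), 1e-8)
            assert np.abs(num - grads[name]).max() / scale < 1e-5, name


@pytest.fixture(scope="module")
def trained(clean_dataset):
    X, y = clean_dataset
    n = len(y)
    cut = int(0.8 * n)
    cfg = TrainConfig(cell=24, fc_size=12, batch_size=32, epochs=25,
                      learning_rate=5e-3, seed=0)
    params, trace = train_gru(X[:cut], y[:cut], X[cut:], y[cut:], cfg)
    return params, trace, (X, y, cut)


class TestTraining:
    def test_loss_trace_finite_every_epoch(self, trained):
        _p, trace, _d = trained
        assert np.isfinite(trace["train_loss"]).all()
        assert len(trace) == 25

    def test_learns_separable_beats(self, trained):
        _p, trace, _d = trained
        assert trace["valid_accuracy"].iloc[-1] >= 0.95

    def test_predict_deterministic_and_normalized(self, trained):
        params, _t, (X, _y, _c) = trained
        p1, h1 = gru_predict(params, X[0])
        p2, h2 = gru_predict(params, X[0])
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(h1, h2)
        assert p1.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p1 >= 0)

    def test_predict_wrong_length_rejected(self, trained):
        params, _t, _d = trained
        with pytest.raises(ValueError):
            gru_predict(params, np.zeros(123))

    def test_serialization_round_trip(self, trained, tmp_path):
        params, _t, (X, _y, _c) = trained
        save_params(tmp_path / "m.npz", params)
        back = load_params(tmp_path / "m.npz")
        p1, _ = gru_predict(params, X[:5])
        p2, _ = gru_predict(back, X[:5])
        np.testing.assert_array_equal(p1, p2)
        assert back.classes == params.classes

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_gru(np.empty((0, 250)), [], np.empty((0, 250)), [],
                      TrainConfig(epochs=1))
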