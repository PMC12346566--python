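"""Network layers versus independent brute-force transcriptions, plus
finite-difference gradient checks and early-stopping semantics."""

import numpy as np
import pytest

from pulmodx import nn

import oracles

RNG = np.random.default_rng(42)
TOL = 1e-6


class TestForwardOracles:
    def test_conv1d_matches_bruteforce(self):
        x = RNG.standard_normal((2, 9, 3))
        layer = nn.Conv1D(3, 4, 5, np.random.default_rng(0))
        got = layer.forward(x)
        want = oracles.conv1d_bruteforce(x, layer.params["W"],
                                         layer.params["b"], 5)
        assert np.max(np.abs(got - want)) < TOL

    def test_batchnorm_matches_bruteforce(self):
        x = RNG.standard_normal((3, 6, 4))
        layer = nn.BatchNorm1D(4)
        layer.params["gamma"] = RNG.uniform(0.5, 1.5, 4)
        layer.params["beta"] = RNG.standard_normal(4)
        got = layer.forward(x, training=True)
        want = oracles.batchnorm_bruteforce(x, layer.params["gamma"],
                                            layer.params["beta"], layer.eps)
        assert np.max(np.abs(got - want)) < TOL

    def test_batchnorm_constant_input_maps_to_zero(self):
        # gamma=1, beta=0: a constant input normalizes to 0
        layer = nn.BatchNorm1D(3)
        out = layer.forward(np.full((2, 5, 3), 7.0), training=True)
        assert np.max(np.abs(out)) < TOL

    def test_maxpool_matches_bruteforce(self):
        x = RNG.standard_normal((2, 7, 3))
        got = nn.MaxPool1D(2).forward(x)
        want = oracles.maxpool_bruteforce(x, 2)
        assert got.shape == (2, 3, 3)
        assert np.max(np.abs(got - want)) < TOL

    def test_lstm_matches_bruteforce(self):
        x = RNG.standard_normal((2, 6, 3)) * 0.5
        layer = nn.LSTM(3, 4, np.random.default_rng(1))
        got = layer.forward(x)
        want = oracles.lstm_bruteforce(x, layer.params["Wx"],
                                       layer.params["Wh"], layer.params["b"])
        assert np.max(np.abs(got - want)) < TOL

    def test_attention_matches_bruteforce(self):
        h = RNG.standard_normal((2, 5, 4))
        layer = nn.AttentionPool(4, 3, np.random.default_rng(2))
        got = layer.forward(h)
        want, alphas = oracles.attention_bruteforce(
            h, layer.params["W1"], layer.params["b1"],
            layer.params["w2"], layer.params["b2"])
        assert np.max(np.abs(got - want)) < TOL
        assert np.max(np.abs(layer.last_alpha - alphas)) < TOL


class TestLSTMCellStep:
    def test_zero_weights_closed_form(self):
        # sigma(0) = 0.5 and tanh(0) = 0, so with all weights zero:
        # f = i = o = 0.5, candidate = 0, c_t = 0.5 c, h = 0.5 tanh(0.5 c)
        H = 3
        weights = {"Wx": np.zeros((2, 4 * H)), "Wh": np.zeros((H, 4 * H)),
                   "b": np.zeros(4 * H)}
        c_prev = np.array([0.4, -1.0, 2.0])
        h, c = nn.lstm_cell_step(np.ones(2), np.zeros(H), c_prev, weights)
        assert np.allclose(c, 0.5 * c_prev)
        assert np.allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_zero_cell_and_candidate_annihilate(self):
        H = 2
        weights = {"Wx": np.zeros((2, 4 * H)), "Wh": np.zeros((H, 4 * H)),
                   "b": np.zeros(4 * H)}
        h, c = nn.lstm_cell_step(np.ones(2), np.zeros(H), np.zeros(H), weights)
        assert np.allclose(c, 0.0)
        assert np.allclose(h, 0.0)

    def test_random_weights_match_reference_recurrence(self):
        rng = np.random.default_rng(3)
        H, F = 4, 3
        weights = {"Wx": rng.normal(0, 0.2, (F, 4 * H)),
                   "Wh": rng.normal(0, 0.2, (H, 4 * H)),
                   "b": rng.normal(0, 0.2, 4 * H)}
        x = rng.standard_normal((1, 5, F))
        h = np.zeros((1, H))
        c = np.zeros((1, H))
        for t in range(5):
            h, c = nn.lstm_cell_step(x[:, t], h, c, weights)
        want = oracles.lstm_bruteforce(x, weights["Wx"], weights["Wh"],
                                       weights["b"])
        assert np.max(np.abs(h - want[:, -1])) < TOL

    def test_dimension_mismatch_errors(self):
        weights = {"Wx": np.zeros((2, 8)), "Wh": np.zeros((2, 8)),
                   "b": np.zeros(8)}
        with pytest.raises(ValueError):
            nn.lstm_cell_step(np.ones(3), np.zeros(2), np.zeros(2), weights)


class TestAttentionProperties:
    def test_softmax_of_equal_scores_is_uniform(self):
        h = np.tile(RNG.standard_normal((1, 1, 4)), (1, 6, 1))
        layer = nn.AttentionPool(4, 3, np.random.default_rng(4))
        layer.forward(h)
        assert np.allclose(layer.last_alpha, 1.0 / 6)

    def test_singleton_sequence(self):
        h = RNG.standard_normal((1, 1, 4))
        layer = nn.AttentionPool(4, 3, np.random.default_rng(5))
        out = layer.forward(h)
        assert np.allclose(layer.last_alpha, [[1.0]])
        assert np.allclose(out, h)

    def test_two_step_hand_softmax(self):
        # scores e = [0, ln 3] -> alpha = [0.25, 0.75]
        alpha = nn.softmax(np.array([[0.0, np.log(3.0)]]), axis=1)
        assert np.allclose(alpha, [[0.25, 0.75]])

    def test_normalization_every_forward(self):
        for seed in range(3):
            h = np.random.default_rng(seed).standard_normal((3, 7, 5))
            layer = nn.AttentionPool(5, 4, np.random.default_rng(seed + 10))
            layer.forward(h)
            assert np.all(layer.last_alpha >= 0)
            assert np.allclose(layer.last_alpha.sum(axis=1), 1.0)


def _gradient_check(layer, x, training=False):
    target = RNG.standard_normal(layer.forward(x, training=training).shape)

    def loss():
        out = layer.forward(x, training=training)
        return 0.5 * np.sum((out - target) ** 2)

    out = layer.forward(x, training=training)
    dx = layer.backward(out - target)
    num_dx = oracles.numerical_gradient(loss, x)
    assert np.max(np.abs(dx - num_dx)) < 1e-5
    for name, p in layer.params.items():
        num = oracles.numerical_gradient(loss, p)
        out = layer.forward(x, training=training)
        layer.backward(out - target)
        assert np.max(np.abs(layer.grads[name] - num)) < 1e-5, name


@pytest.mark.parametrize("factory,shape,training", [
    (lambda r: nn.Conv1D(3, 4, 3, r), (2, 6, 3), False),
    (lambda r: nn.BatchNorm1D(3), (2, 5, 3), True),
    (lambda r: nn.MaxPool1D(2), (2, 6, 3), False),
    (lambda r: nn.LSTM(3, 4, r, return_sequences=True), (2, 5, 3), False),
    (lambda r: nn.LSTM(3, 4, r, return_sequences=False), (2, 5, 3), False),
    (lambda r: nn.AttentionPool(3, 4, r), (2, 5, 3), False),
    (lambda r: nn.AttentionPool(3, 4, r, mode="uniform"), (2, 5, 3), False),
    (lambda r: nn.GlobalAvgPool(), (2, 5, 3), False),
    (lambda r: nn.Dense(4, 3, r, activation="relu"), (5, 4), False),
])
def test_backward_matches_finite_differences(factory, shape, training):
    layer = factory(np.random.default_rng(11))
    x = np.random.default_rng(12).standard_normal(shape)
    _gradient_check(layer, x, training=training)


class TestLossAndOptimizer:
    def test_softmax_cross_entropy_gradient(self):
        logits = RNG.standard_normal((4, 8))
        y = np.eye(8)[[0, 3, 5, 7]]
        loss, grad = nn.softmax_cross_entropy(logits, y)

        def f():
            return nn.softmax_cross_entropy(logits, y)[0]

        num = oracles.numerical_gradient(f, logits)
        assert np.max(np.abs(grad - num)) < 1e-6
        assert loss > 0

    def test_adam_decreases_simple_loss(self):
        rng = np.random.default_rng(0)
        model = nn.Sequential([nn.Dense(3, 2, rng)])
        opt = nn.Adam(model, lr=0.05)
        x = rng.standard_normal((16, 3))
        y = np.eye(2)[(x[:, 0] > 0).astype(int)]
        losses = []
        for _ in range(50):
            logits = model.forward(x, training=True)
            loss, dl = nn.softmax_cross_entropy(logits, y)
            model.backward(dl)
            opt.step()
            losses.append(loss)
        assert losses[-1] < 0.5 * losses[0]


class TestEarlyStopping:
    def test_scripted_schedule_stops_at_epoch_12(self):
        # val losses 1.0, 0.9 then ten 0.9s: stop at epoch 12, best at 2
        stopper = nn.EarlyStopping(patience=10)
        schedule = [1.0, 0.9] + [0.9] * 10
        stopped_at = None
        for epoch, loss in enumerate(schedule, start=1):
            if stopper.update(epoch, loss, weights=epoch):
                stopped_at = epoch
                break
        assert stopped_at == 12
        assert stopper.best_epoch == 2
        assert stopper.best_weights == 2

    def test_improvement_resets_patience(self):
        stopper = nn.EarlyStopping(patience=3)
        for epoch, loss in enumerate([1.0, 0.9, 0.95, 0.85, 0.9, 0.9], 1):
            assert not stopper.update(epoch, loss)
        assert stopper.best_epoch == 4

    def test_weight_restoration_round_trip(self):
        rng = np.random.default_rng(1)
        model = nn.Sequential([nn.Dense(3, 2, rng), nn.BatchNorm1D(2)])
        saved = model.get_weights()
        before = model.forward(np.ones((1, 3)))
        model.layers[0].params["W"] += 1.0
        assert not np.allclose(model.forward(np.ones((1, 3))), before)
        model.set_weights(saved)
        assert np.allclose(model.forward(np.ones((1, 3))), before)
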