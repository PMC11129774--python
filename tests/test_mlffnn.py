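import numpy as np
import pandas as pd
import pytest

from qualinear import (
    ConfigError,
    DataError,
    DivergenceError,
    MLPNetwork,
    NeuralNetRegressor,
    min_max_scale,
    mse_net,
)


def _single_path_network():
    """1-1-1 chain with unit weights and zero biases."""
    return MLPNetwork(
        layer_sizes=(1, 1, 1),
        weights=[np.array([[1.0]]), np.array([[1.0]])],
        biases=[np.array([0.0]), np.array([0.0])],
    )


class TestScaling:
    def test_maps_column_to_unit_interval(self):
        scaled, params = min_max_scale(pd.DataFrame({"x": [2.0, 4.0, 6.0]}))
        assert scaled["x"].tolist() == [0.0, 0.5, 1.0]

    def test_unit_interval_column_unchanged(self):
        frame = pd.DataFrame({"x": [0.0, 0.25, 1.0]})
        scaled, _ = min_max_scale(frame)
        assert scaled["x"].tolist() == frame["x"].tolist()

    def test_roundtrip_error_below_1e12(self, rng):
        frame = pd.DataFrame(rng.normal(5, 20, size=(50, 3)), columns=list("abc"))
        scaled, params = min_max_scale(frame)
        assert ((scaled >= 0) & (scaled <= 1)).all().all()
        back = params.inverse(scaled)
        assert np.abs(back.to_numpy() - frame.to_numpy()).max() < 1e-12

    def test_constant_column_rejected(self):
        with pytest.raises(ConfigError, match="constant"):
            min_max_scale(pd.DataFrame({"x": [1.0, 1.0]}))


class TestForward:
    def test_zero_weights_output_equals_bias(self, rng):
        net = MLPNetwork(
            layer_sizes=(2, 3, 2, 1),
            weights=[np.zeros((2, 3)), np.zeros((3, 2)), np.zeros((2, 1))],
            biases=[np.zeros(3), np.zeros(2), np.array([0.7])],
        )
        X = rng.normal(size=(5, 2))
        assert net.forward(X) == pytest.approx(np.full(5, 0.7))

    def test_single_path_logistic_value(self):
        # logistic(1) = 0.7310586 through the hidden node, linear output
        out = _single_path_network().forward([[1.0]])
        assert out[0] == pytest.approx(0.7310586, abs=1e-7)

    def test_symmetric_weights_invariant_under_input_swap(self):
        net = MLPNetwork(
            layer_sizes=(2, 2, 1),
            weights=[np.full((2, 2), 0.3), np.array([[0.5], [-0.2]])],
            biases=[np.array([0.1, -0.1]), np.array([0.0])],
        )
        assert net.forward([[0.2, 0.9]]) == pytest.approx(net.forward([[0.9, 0.2]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            _single_path_network().forward([[1.0, 2.0]])


class TestGradients:
    def test_backprop_matches_central_differences(self, rng):
        net = MLPNetwork(
            layer_sizes=(3, 3, 2, 1),
            weights=[rng.uniform(-0.5, 0.5, s) for s in [(3, 3), (3, 2), (2, 1)]],
            biases=[rng.uniform(-0.5, 0.5, s) for s in [3, 2, 1]],
        )
        X = rng.uniform(0, 1, size=(12, 3))
        y = rng.uniform(0, 1, size=12)
        _, gW, gb = net.loss_and_gradients(X, y)
        eps = 1e-6

        def loss():
            return net.loss_and_gradients(X, y)[0]

        for params, grads in ((net.weights, gW), (net.biases, gb)):
            for P, G in zip(params, grads):
                it = np.nditer(P, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = P[idx]
                    P[idx] = orig + eps
                    up = loss()
                    P[idx] = orig - eps
                    down = loss()
                    P[idx] = orig
                    fd = (up - down) / (2 * eps)
                    denom = max(abs(fd), abs(G[idx]), 1e-8)
                    assert abs(fd - G[idx]) / denom < 1e-6


class TestTraining:
    def _identity_frame(self, n=64):
        x = np.linspace(0.0, 1.0, n)
        return pd.DataFrame({"x": x, "y": x})

    def test_learns_identity_map(self):
        frame = self._identity_frame()
        res = NeuralNetRegressor(frame, "y").fit(seed=0, max_epochs=2000)
        assert res.final_loss < 1e-3

    def test_zero_epochs_returns_initialization(self):
        frame = self._identity_frame()
        model = NeuralNetRegressor(frame, "y")
        res = model.fit(seed=3, max_epochs=0)
        ref = model.fit(seed=3, max_epochs=0)
        for a, b in zip(res.network.weights, ref.network.weights):
            assert (a == b).all()
        assert res.stop_reason == "max_epochs"

    def test_same_seed_bit_identical_trajectories(self):
        frame = self._identity_frame()
        r1 = NeuralNetRegressor(frame, "y").fit(seed=7, max_epochs=200)
        r2 = NeuralNetRegressor(frame, "y").fit(seed=7, max_epochs=200)
        assert r1.loss_history == r2.loss_history
        for a, b in zip(r1.network.weights, r2.network.weights):
            assert (a == b).all()

    def test_loss_monotone_descent_at_small_learning_rate(self):
        frame = self._identity_frame(32)
        res = NeuralNetRegressor(frame, "y").fit(
            seed=1, learning_rate=1e-3, max_epochs=300)
        h = res.loss_history
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))
        assert res.final_loss <= h[0]

    def test_divergence_raises_helpful_error(self):
        frame = self._identity_frame(16)
        with pytest.raises(DivergenceError, match="learning rate"):
            NeuralNetRegressor(frame, "y").fit(
                seed=0, learning_rate=1e6, max_epochs=500)

    def test_beats_mean_predictor_on_linear_data(self):
        # pipeline-style data: linear signal + small noise, scaled to [0,1]
        from qualinear import SplitSpec, SyntheticConfig, encode_dummies, generate, split_train_test
        ds = generate(SyntheticConfig(n=300, noise_sd=1.0, seed=11))
        encoded, _ = encode_dummies(ds, "treatment")
        scaled, _ = min_max_scale(encoded.frame)
        train, test = split_train_test(scaled, SplitSpec(seed=5))
        res = NeuralNetRegressor(train, "effectiveness").fit(seed=2, max_epochs=2000)
        mse_test = res.test_mse(test)
        assert mse_test < float(np.var(test["effectiveness"]))


class TestMSENet:
    def test_perfect_predictions_zero(self):
        net = MLPNetwork((1, 1), [np.array([[0.0]])], [np.array([0.5])])
        frame = pd.DataFrame({"x": [0.1, 0.9], "y": [0.5, 0.5]})
        assert mse_net(net, frame, "y") == 0.0

    def test_constant_half_on_symmetric_targets(self):
        net = MLPNetwork((1, 1), [np.array([[0.0]])], [np.array([0.5])])
        frame = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0]})
        assert mse_net(net, frame, "y") == pytest.approx(0.25)

    def test_empty_test_set_rejected(self):
        net = MLPNetwork((1, 1), [np.array([[0.0]])], [np.array([0.5])])
        with pytest.raises(DataError):
            mse_net(net, pd.DataFrame({"x": [], "y": []}), "y")

    def test_unscaled_variant_uses_inverse_transform(self):
        frame = pd.DataFrame({"x": [2.0, 4.0, 6.0], "y": [10.0, 20.0, 30.0]})
        scaled, params = min_max_scale(frame)
        net = MLPNetwork((1, 1), [np.array([[0.0]])], [np.array([0.5])])
        scaled_mse = mse_net(net, scaled, "y")
        raw_mse = mse_net(net, scaled, "y", scaling=params)
        assert raw_mse == pytest.approx(scaled_mse * 20.0 ** 2)

    def test_serialization_roundtrip(self):
        net = _single_path_network()
        clone = MLPNetwork.from_dict(net.to_dict())
        assert clone.forward([[0.3]]) == pytest.approx(net.forward([[0.3]]))
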