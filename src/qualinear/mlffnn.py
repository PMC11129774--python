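"""Multilayer feedforward neural network used as a regression validator.

Architecture: inputs -> hidden layer of 3 logistic units -> hidden layer of
2 logistic units -> single linear output.  Data are min-max scaled to [0,1]
first; the test mean squared error is reported on the scaled response (the
published convention), with an unscaled variant available via the inverse
transform.

Training is full-batch gradient descent on the squared-error loss with a
gradient-norm stopping rule.  It is deliberately simple and fully
deterministic given a seed: the network plays a validation role here, not a
performance one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, DataError, DivergenceError

__all__ = [
    "ScalingParams",
    "min_max_scale",
    "MLPNetwork",
    "NeuralNetRegressor",
    "NeuralNetResults",
    "mse_net",
]


@dataclass(frozen=True)
class ScalingParams:
    """Per-column minima and ranges for min-max normalization."""

    minima: pd.Series
    ranges: pd.Series

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        cols = self.minima.index
        return (frame[cols] - self.minima) / self.ranges

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in frame.columns if c in self.minima.index]
        return frame[cols] * self.ranges[cols] + self.minima[cols]

    def inverse_column(self, values, column: str) -> np.ndarray:
        return np.asarray(values, dtype=float) * float(self.ranges[column]) \
            + float(self.minima[column])


def min_max_scale(frame: pd.DataFrame):
    """Scale every column to [0, 1]; returns (scaled frame, ScalingParams).

    Raises :class:`ConfigError` for constant columns (zero range).
    """
    minima = frame.min()
    maxima = frame.max()
    ranges = maxima - minima
    constant = ranges[ranges == 0].index.tolist()
    if constant:
        raise ConfigError(f"constant column(s) cannot be min-max scaled: {constant}")
    params = ScalingParams(minima=minima.astype(float), ranges=ranges.astype(float))
    return params.transform(frame), params


@dataclass
class MLPNetwork:
    """Layered weights/biases: logistic hidden activations, identity output.

    ``weights[l]`` has shape (fan_in, fan_out); ``biases[l]`` shape (fan_out,).
    """

    layer_sizes: tuple
    weights: list
    biases: list
    hidden_activation: str = "logistic"
    output_activation: str = "identity"

    def _check(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.layer_sizes[0]:
            raise DataError(
                f"input has {X.shape[1]} features, network expects {self.layer_sizes[0]}"
            )
        return X

    def forward(self, X) -> np.ndarray:
        """Deterministic forward pass; returns one output per row."""
        A = self._check(X)
        last = len(self.weights) - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            Z = A @ W + b
            A = Z if l == last else expit(Z)
        return A.ravel()

    def _forward_cached(self, X):
        """Activations per layer, for backpropagation."""
        acts = [X]
        last = len(self.weights) - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            Z = acts[-1] @ W + b
            acts.append(Z if l == last else expit(Z))
        return acts

    def loss_and_gradients(self, X, y):
        """Mean-squared-error loss and its analytic gradients.

        Returns ``(loss, grads_W, grads_b)`` with gradients matching the
        parameter shapes; used both by training and by finite-difference
        verification.
        """
        X = self._check(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        with np.errstate(over="ignore", invalid="ignore"):
            return self._loss_and_gradients(X, y, n)

    def _loss_and_gradients(self, X, y, n):
        acts = self._forward_cached(X)
        yhat = acts[-1].ravel()
        resid = yhat - y
        loss = float(np.mean(resid ** 2))
        # output layer is linear: dL/dZ_out = 2 r / n
        delta = (2.0 * resid / n)[:, None]
        grads_W, grads_b = [], []
        for l in range(len(self.weights) - 1, -1, -1):
            A_prev = acts[l]
            grads_W.append(A_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if l > 0:
                A_l = acts[l]  # logistic activation of layer l
                delta = (delta @ self.weights[l].T) * A_l * (1.0 - A_l)
        grads_W.reverse()
        grads_b.reverse()
        return loss, grads_W, grads_b

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d) -> "MLPNetwork":
        return cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(W, dtype=float) for W in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            hidden_activation=d.get("hidden_activation", "logistic"),
            output_activation=d.get("output_activation", "identity"),
        )


def _init_network(n_inputs, hidden, rng) -> MLPNetwork:
    sizes = (n_inputs, *hidden, 1)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-0.5, 0.5, size=fan_out))
    return MLPNetwork(layer_sizes=sizes, weights=weights, biases=biases)


class NeuralNetRegressor:
    """Feedforward-network regression model on min-max-scaled data.

    Parameters
    ----------
    train_scaled : pandas.DataFrame
        Training table with every column already scaled to [0, 1].
    response_name : str
        Column to predict; all other columns are inputs.
    hidden : tuple of int
        Hidden layer widths (default ``(3, 2)``).
    """

    def __init__(self, train_scaled: pd.DataFrame, response_name: str,
                 hidden: tuple = (3, 2)):
        if response_name not in train_scaled.columns:
            raise ConfigError(f"response column {response_name!r} not in data")
        if len(train_scaled) == 0:
            raise DataError("empty training set")
        self.response_name = response_name
        self.feature_names = [c for c in train_scaled.columns if c != response_name]
        self.X = train_scaled[self.feature_names].to_numpy(dtype=float)
        self.y = train_scaled[response_name].to_numpy(dtype=float)
        self.hidden = tuple(int(h) for h in hidden)

    def n_parameters(self) -> int:
        sizes = (len(self.feature_names), *self.hidden, 1)
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))

    def fit(self, seed: int = 0, learning_rate: float = 0.5,
            max_epochs: int = 2000, tol: float = 0.01,
            rng: np.random.Generator | None = None) -> "NeuralNetResults":
        """Full-batch gradient descent until the gradient norm drops below
        ``tol`` or ``max_epochs`` is reached.

        The stopping rule measures the gradient of the *total* (summed)
        squared error, the scale on which a threshold of 0.01 conventionally
        signals convergence; descent steps themselves use the mean-scale
        gradient so the learning rate is insensitive to the sample size.
        ``max_epochs=0`` returns the random initialization untouched, which
        is occasionally useful as a null baseline.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        net = _init_network(len(self.feature_names), self.hidden, rng)
        history = []
        stop = "max_epochs"
        for _ in range(max_epochs):
            loss, gW, gb = net.loss_and_gradients(self.X, self.y)
            if not np.isfinite(loss):
                raise DivergenceError(
                    "training loss became non-finite; try a smaller learning rate"
                )
            history.append(loss)
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in gW)
                            + sum(float((g ** 2).sum()) for g in gb))
            if len(self.y) * gnorm < tol:  # sum-of-squares scale
                stop = "gradient_norm"
                break
            for W, g in zip(net.weights, gW):
                W -= learning_rate * g
            for b, g in zip(net.biases, gb):
                b -= learning_rate * g
        final_loss = net.loss_and_gradients(self.X, self.y)[0]
        return NeuralNetResults(self, net, history, final_loss, stop)


@dataclass
class NeuralNetResults:
    """Trained network plus its training trajectory."""

    model: NeuralNetRegressor
    network: MLPNetwork
    loss_history: list = field(default_factory=list)
    final_loss: float = float("nan")
    stop_reason: str = ""

    def predict(self, scaled_frame: pd.DataFrame) -> np.ndarray:
        """Predictions on the scaled response for a scaled covariate table.

        Only the covariate columns are fed to the network, even if the
        response column is present in the frame.
        """
        X = scaled_frame[self.model.feature_names].to_numpy(dtype=float)
        return self.network.forward(X)

    def test_mse(self, test_scaled: pd.DataFrame,
                 scaling: ScalingParams | None = None) -> float:
        """Scaled-response test MSE; pass ``scaling`` for the unscaled variant."""
        return mse_net(self.network, test_scaled, self.model.response_name,
                       feature_names=self.model.feature_names, scaling=scaling)


def mse_net(network: MLPNetwork, test_scaled: pd.DataFrame, response_name: str,
            feature_names=None, scaling: ScalingParams | None = None) -> float:
    """Test-set mean squared error of the network.

    On the scaled response by default (dimensionless); if ``scaling`` is
    given, both predictions and targets are back-transformed first, making
    the result unit-comparable to a raw-scale regression MSE.
    """
    if len(test_scaled) == 0:
        raise DataError("empty test set")
    if feature_names is None:
        feature_names = [c for c in test_scaled.columns if c != response_name]
    X = test_scaled[feature_names].to_numpy(dtype=float)
    y = test_scaled[response_name].to_numpy(dtype=float)
    yhat = network.forward(X)
    if scaling is not None:
        y = scaling.inverse_column(y, response_name)
        yhat = scaling.inverse_column(yhat, response_name)
    return float(np.mean((y - yhat) ** 2))
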