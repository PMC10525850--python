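"""Single-hidden-layer backpropagation network for angle regression.

The head maps a feature vector y to an angle estimate

    theta_hat = W_out * tansig(W_in y + b_in) + b_out

with tansig(x) = 2 / (1 + exp(-2x)) - 1 (identical to tanh) in the hidden
layer and a linear (purelin) output.  Training is batch gradient descent on
the mean squared error.  Labels are standardized internally and the inverse
transform is folded into the output weights, so the trained parameters map
features straight to degrees.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

__all__ = ["BpnnParams", "BpnnTrainConfig", "bpnn_forward", "train_bpnn"]


@dataclass(frozen=True)
class BpnnParams:
    """Weights of the three-layer perceptron (input -> 12 tansig -> linear)."""

    W_in: np.ndarray  # (hidden, input)
    b_in: np.ndarray  # (hidden,)
    W_out: np.ndarray  # (1, hidden)
    b_out: float

    def __post_init__(self) -> None:
        W_in = np.asarray(self.W_in, dtype=float)
        b_in = np.asarray(self.b_in, dtype=float)
        W_out = np.asarray(self.W_out, dtype=float)
        if W_in.ndim != 2 or b_in.shape != (W_in.shape[0],):
            raise ValueError("inconsistent input-layer shapes")
        if W_out.shape != (1, W_in.shape[0]):
            raise ValueError("inconsistent output-layer shapes")
        object.__setattr__(self, "W_in", W_in)
        object.__setattr__(self, "b_in", b_in)
        object.__setattr__(self, "W_out", W_out)
        object.__setattr__(self, "b_out", float(self.b_out))

    @property
    def hidden_size(self) -> int:
        return self.W_in.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_in.shape[1]


@dataclass(frozen=True)
class BpnnTrainConfig:
    max_iter: int = 1000
    learning_rate: float = 0.01
    hidden_size: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 0 or self.learning_rate <= 0 or self.hidden_size < 1:
            raise ValueError("invalid BPNN training configuration")


def tansig(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


def bpnn_forward(params: BpnnParams, y: np.ndarray) -> np.ndarray:
    """Angle estimate(s) in degrees; accepts a vector or an (n, d) matrix."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != params.input_size:
        raise ValueError("feature dimension does not match W_in")
    out = tansig(Y @ params.W_in.T + params.b_in) @ params.W_out.T + params.b_out
    out = out[:, 0]
    return float(out[0]) if single else out


def _init(input_size: int, hidden_size: int, rng: np.random.Generator):
    W_in = 0.1 * rng.standard_normal((hidden_size, input_size))
    b_in = np.zeros(hidden_size)
    W_out = 0.1 * rng.standard_normal((1, hidden_size))
    b_out = 0.0
    return W_in, b_in, W_out, b_out


def train_bpnn(
    features: np.ndarray, labels: np.ndarray, config: BpnnTrainConfig = BpnnTrainConfig()
) -> BpnnParams:
    """Fit the head by full-batch gradient descent on the MSE.

    The learning rate adapts multiplicatively (grown 5% after an improving
    step, cut 30% and the step rejected after a worsening one), which keeps
    plain gradient descent stable across feature scales while remaining
    fully deterministic given the seed.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if len(X) != len(y) or len(y) < 2:
        raise ValueError("need at least two aligned samples")

    y_mean = float(y.mean())
    y_std = float(y.std())
    if y_std == 0.0:
        y_std = 1.0
    z = (y - y_mean) / y_std

    # standardize inputs as well (DBN codes can sit in narrow saturated
    # subintervals); the affine map is folded back into W_in/b_in below
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std[x_std == 0.0] = 1.0
    X = (X - x_mean) / x_std

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 21]))
    W_in, b_in, W_out, b_out = _init(X.shape[1], config.hidden_size, rng)

    lr = config.learning_rate
    n = len(X)

    def hidden_and_err(Wi, bi, Wo, bo):
        H = tansig(X @ Wi.T + bi)
        err = (H @ Wo.T)[:, 0] + bo - z
        return H, err

    H, err = hidden_and_err(W_in, b_in, W_out, b_out)
    prev = float(np.mean(err**2))
    for _ in range(config.max_iter):
        dout = 2.0 * err / n
        gWo = dout[None, :] @ H
        gbo = dout.sum()
        dh = np.outer(dout, W_out[0]) * (1.0 - H**2)
        gWi = dh.T @ X
        gbi = dh.sum(axis=0)

        cand = (W_in - lr * gWi, b_in - lr * gbi, W_out - lr * gWo, b_out - lr * gbo)
        Hc, errc = hidden_and_err(*cand)
        new = float(np.mean(errc**2))
        if new <= prev * 1.0001:
            W_in, b_in, W_out, b_out = cand
            H, err, prev = Hc, errc, new
            lr *= 1.05
        else:
            lr *= 0.7

    # fold input standardization into the first layer and label
    # de-standardization into the linear output layer
    return BpnnParams(
        W_in=W_in / x_std,
        b_in=b_in - W_in @ (x_mean / x_std),
        W_out=W_out * y_std,
        b_out=b_out * y_std + y_mean,
    )
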