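"""Restricted Boltzmann machines and the deep belief network built on them.

An RBM over visible units v (length m) and hidden units h (length n) has
energy

    E(v, h) = -v^T W h - b^T v - c^T h

with joint probability P(v, h) = exp(-E) / Z.  Because the bipartite graph
has no intra-layer couplings the conditionals factorize:

    P(h_j = 1 | v) = sigma(W^T v + c)_j
    P(v_i = 1 | h) = sigma(W h + b)_i

Training maximizes the data log-likelihood; the gradient is approximated by
contrastive divergence (CD-k): the positive statistics come from the data,
the negative ones from k steps of Gibbs sampling started at the data.

The DBN stacks four RBMs trained greedily (each on the hidden probabilities
of the one below), then unrolls encoder + transposed-decoder into a deep
autoencoder that is fine-tuned by backpropagation on the reconstruction
error.  Normalized real-valued features in [0, 1] are fed to the Bernoulli
units as probabilities: hidden states are sampled binary during CD, visible
reconstructions are kept as probabilities.

``exact_loglik_gradient`` computes the true likelihood gradient by state
enumeration for tiny RBMs and exists purely as an independent check on CD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "RbmParams",
    "DbnTrainConfig",
    "DbnModel",
    "sigmoid",
    "hidden_probs",
    "visible_probs",
    "energy",
    "joint_distribution",
    "cd_update",
    "exact_loglik_gradient",
    "pretrain_dbn",
    "fine_tune_autoencoder",
    "transform",
    "reconstruct",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # expit is overflow-safe at large |x|
    return expit(x)


@dataclass(frozen=True)
class RbmParams:
    """One RBM: W is visible x hidden, b the visible bias, c the hidden bias."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        b = np.asarray(self.b, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if W.ndim != 2 or b.shape != (W.shape[0],) or c.shape != (W.shape[1],):
            raise ValueError("inconsistent RBM parameter shapes")
        if not (np.isfinite(W).all() and np.isfinite(b).all() and np.isfinite(c).all()):
            raise ValueError("RBM parameters must be finite")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class DbnTrainConfig:
    """RBM/DBN training hyperparameters.

    The contrastive-divergence learning rate is 0.01 and each RBM trains
    for 200 epochs; minibatches of 32 keep the updates cheap.  Fine-tuning
    runs ``fine_tune_epochs`` full-batch gradient steps on the unrolled
    autoencoder, starting from ``fine_tune_lr`` with multiplicative
    learning-rate adaptation.
    """

    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 32
    cd_k: int = 1
    fine_tune_epochs: int = 500
    fine_tune_lr: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.fine_tune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 0 or self.fine_tune_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.cd_k < 1:
            raise ValueError("cd_k must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class DbnModel:
    """Greedily pretrained RBM stack, optionally fine-tuned as an autoencoder.

    ``encoder`` / ``decoder`` hold the unrolled (weight, bias) pairs after
    fine-tuning; until then :func:`transform` uses the RBM weights directly.
    """

    layer_sizes: List[int]
    rbms: List[RbmParams]
    encoder: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None
    decoder: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None
    trained: bool = False

    def __post_init__(self) -> None:
        sizes = [self.rbms[0].n_visible] + [r.n_hidden for r in self.rbms]
        if sizes != list(self.layer_sizes):
            raise ValueError("RBM shapes do not chain to layer_sizes")

    @property
    def fine_tuned(self) -> bool:
        return self.encoder is not None

    @property
    def top_width(self) -> int:
        return self.layer_sizes[-1]


def hidden_probs(rbm: RbmParams, v: np.ndarray) -> np.ndarray:
    """P(h = 1 | v); accepts a vector or a (batch, m) matrix."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != rbm.n_visible:
        raise ValueError("visible vector has wrong length")
    return sigmoid(v @ rbm.W + rbm.c)


def visible_probs(rbm: RbmParams, h: np.ndarray) -> np.ndarray:
    """P(v = 1 | h); accepts a vector or a (batch, n) matrix."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != rbm.n_hidden:
        raise ValueError("hidden vector has wrong length")
    return sigmoid(h @ rbm.W.T + rbm.b)


def energy(rbm: RbmParams, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) = -v^T W h - b^T v - c^T h."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (rbm.n_visible,) or h.shape != (rbm.n_hidden,):
        raise ValueError("v/h shapes do not match the RBM")
    return float(-(v @ rbm.W @ h) - rbm.b @ v - rbm.c @ h)


def _all_states(k: int) -> np.ndarray:
    return np.array(list(itertools.product([0.0, 1.0], repeat=k)))


def joint_distribution(rbm: RbmParams) -> np.ndarray:
    """Exhaustive P(v, h) as a (2^m, 2^n) matrix (tiny RBMs only)."""
    if rbm.n_visible + rbm.n_hidden > 16:
        raise ValueError("RBM too large to enumerate")
    V = _all_states(rbm.n_visible)
    H = _all_states(rbm.n_hidden)
    # -E(v,h) for every state pair
    negE = V @ rbm.W @ H.T + (V @ rbm.b)[:, None] + (H @ rbm.c)[None, :]
    p = np.exp(negE)
    return p / p.sum()


def cd_update(
    rbm: RbmParams,
    batch: np.ndarray,
    learning_rate: float,
    cd_k: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> RbmParams:
    """One CD-k parameter update from a batch of visible vectors in [0, 1].

    Positive statistics use the data and hidden probabilities; the Gibbs
    chain samples hidden states binary while visible reconstructions stay
    probability-valued.  Updates are averaged over the batch.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    if batch.min() < 0.0 or batch.max() > 1.0:
        raise ValueError("visible values must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()

    n = batch.shape[0]
    h0 = hidden_probs(rbm, batch)
    h_sample = (rng.random(h0.shape) < h0).astype(float)
    vk = batch
    for _ in range(cd_k):
        vk = visible_probs(rbm, h_sample)
        hk = hidden_probs(rbm, vk)
        h_sample = (rng.random(hk.shape) < hk).astype(float)

    dW = (batch.T @ h0 - vk.T @ hk) / n
    db = np.mean(batch - vk, axis=0)
    dc = np.mean(h0 - hk, axis=0)
    return RbmParams(
        W=rbm.W + learning_rate * dW,
        b=rbm.b + learning_rate * db,
        c=rbm.c + learning_rate * dc,
    )


def exact_loglik_gradient(
    rbm: RbmParams, data: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of the mean data log-likelihood, by state enumeration.

    The data term uses the closed-form conditional E[h | v]; the model term
    sums over all 2^m visible states with P(v) proportional to
    exp(b.v) * prod_j (1 + exp(c_j + W_j . v)).  Only valid for m + n <= 16.
    """
    if rbm.n_visible + rbm.n_hidden > 16:
        raise ValueError("RBM too large to enumerate")
    data = np.atleast_2d(np.asarray(data, dtype=float))

    hp = hidden_probs(rbm, data)
    dW_data = data.T @ hp / len(data)
    db_data = data.mean(axis=0)
    dc_data = hp.mean(axis=0)

    V = _all_states(rbm.n_visible)
    act = V @ rbm.W + rbm.c
    log_pv = V @ rbm.b + np.sum(np.logaddexp(0.0, act), axis=1)
    pv = np.exp(log_pv - log_pv.max())
    pv /= pv.sum()
    hv = sigmoid(act)
    dW_model = V.T @ (pv[:, None] * hv)
    db_model = pv @ V
    dc_model = pv @ hv

    return dW_data - dW_model, db_data - db_model, dc_data - dc_model


def _init_rbm(m: int, n: int, rng: np.random.Generator) -> RbmParams:
    # fan-scaled uniform init (the sigmoid variant of Glorot scaling): with
    # only 4 visible units a near-zero init collapses every hidden layer to
    # sigma(c) and leaves the stacked code constant across samples
    scale = 4.0 * np.sqrt(6.0 / (m + n))
    return RbmParams(W=rng.uniform(-scale, scale, (m, n)), b=np.zeros(m), c=np.zeros(n))


def _train_rbm(
    X: np.ndarray, n_hidden: int, config: DbnTrainConfig, rng: np.random.Generator
) -> RbmParams:
    # same CD-k recursion as cd_update, inlined on raw arrays so the hot
    # loop skips per-update parameter validation
    init = _init_rbm(X.shape[1], n_hidden, rng)
    W, b, c = init.W.copy(), init.b.copy(), init.c.copy()
    n = len(X)
    lr = config.learning_rate
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            m = len(batch)
            h0 = expit(batch @ W + c)
            hs = (rng.random(h0.shape) < h0).astype(float)
            for _k in range(config.cd_k):
                vk = expit(hs @ W.T + b)
                hk = expit(vk @ W + c)
                hs = (rng.random(hk.shape) < hk).astype(float)
            W += lr * ((batch.T @ h0 - vk.T @ hk) / m)
            b += lr * np.mean(batch - vk, axis=0)
            c += lr * np.mean(h0 - hk, axis=0)
    return RbmParams(W=W, b=b, c=c)


def pretrain_dbn(
    layer_sizes: Sequence[int], features: np.ndarray, config: DbnTrainConfig
) -> DbnModel:
    """Greedy layer-wise pretraining of the RBM stack.

    Each RBM trains for ``config.epochs`` on the hidden probabilities of
    the (frozen) layer below; the first trains on the features themselves.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    layer_sizes = list(int(s) for s in layer_sizes)
    if layer_sizes[0] != features.shape[1]:
        raise ValueError("layer_sizes[0] must equal the feature dimension")
    if any(s < 1 for s in layer_sizes):
        raise ValueError("layer sizes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    rbms = []
    X = features
    for n_hidden in layer_sizes[1:]:
        rbm = _train_rbm(X, n_hidden, config, rng)
        rbms.append(rbm)
        X = hidden_probs(rbm, X)
    return DbnModel(layer_sizes=layer_sizes, rbms=rbms, trained=True)


def _forward(layers, X):
    acts = [X]
    for W, bias in layers:
        acts.append(sigmoid(acts[-1] @ W + bias))
    return acts


def fine_tune_autoencoder(
    dbn: DbnModel, features: np.ndarray, config: DbnTrainConfig
) -> DbnModel:
    """Unroll the stack into an autoencoder and fine-tune by backprop.

    The decoder is initialized as the transposed encoder (classic unrolled
    autoencoder) and untied during training; the loss is the mean squared
    reconstruction error, minimized by minibatch gradient descent.
    """
    if not dbn.trained:
        raise ValueError("fine_tune_autoencoder requires a pretrained model")
    X = np.atleast_2d(np.asarray(features, dtype=float))

    enc = [(r.W.copy(), r.c.copy()) for r in dbn.rbms]
    dec = [(r.W.T.copy(), r.b.copy()) for r in reversed(dbn.rbms)]
    layers = enc + dec

    n = len(X)
    lr = config.fine_tune_lr
    acts = _forward(layers, X)
    prev = float(np.mean(np.sum((acts[-1] - X) ** 2, axis=1)))
    for _ in range(config.fine_tune_epochs):
        # backprop of the per-sample squared reconstruction error
        delta = (acts[-1] - X) * (2.0 / n)
        delta = delta * acts[-1] * (1.0 - acts[-1])
        grads = [None] * len(layers)
        for li in range(len(layers) - 1, -1, -1):
            W, bias = layers[li]
            grads[li] = (acts[li].T @ delta, delta.sum(axis=0))
            if li > 0:
                delta = (delta @ W.T) * acts[li] * (1.0 - acts[li])
        cand = [
            (W - lr * gW, bias - lr * gb)
            for (W, bias), (gW, gb) in zip(layers, grads)
        ]
        cand_acts = _forward(cand, X)
        new = float(np.mean(np.sum((cand_acts[-1] - X) ** 2, axis=1)))
        # multiplicative learning-rate adaptation keeps full-batch descent
        # stable across architectures; a worsening step is rejected
        if new <= prev * 1.0001:
            layers, acts, prev = cand, cand_acts, new
            lr *= 1.05
        else:
            lr *= 0.7

    k = len(enc)
    return DbnModel(
        layer_sizes=list(dbn.layer_sizes),
        rbms=list(dbn.rbms),
        encoder=layers[:k],
        decoder=layers[k:],
        trained=True,
    )


def transform(dbn: DbnModel, features: np.ndarray) -> np.ndarray:
    """Deterministic encoder pass; output has ``top_width`` columns in (0, 1)."""
    if not dbn.trained:
        raise ValueError("transform requires a trained model")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != dbn.layer_sizes[0]:
        raise ValueError("feature dimension does not match the model")
    if dbn.encoder is not None:
        return _forward(dbn.encoder, X)[-1]
    for rbm in dbn.rbms:
        X = hidden_probs(rbm, X)
    return X


def reconstruct(dbn: DbnModel, features: np.ndarray) -> np.ndarray:
    """Encoder + decoder round trip (autoencoder reconstruction)."""
    if not dbn.trained:
        raise ValueError("reconstruct requires a trained model")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if dbn.encoder is not None:
        return _forward(dbn.decoder, _forward(dbn.encoder, X)[-1])[-1]
    code = transform(dbn, X)
    for rbm in reversed(dbn.rbms):
        code = visible_probs(rbm, code)
    return code
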