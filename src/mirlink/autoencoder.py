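"""Fully connected autoencoder for latent feature augmentation.

The 128-d pair embedding x (miRNA || gene) is min-max scaled to [0,1],
compressed by a three-layer ReLU encoder to a latent vector z = f(x) =
sigma(Wx + b) applied layer-wise, and reconstructed by a three-layer
decoder x_hat = g(z) = sigma'(W'z + b') whose output activation is a
sigmoid (hence the [0,1] scaling). Training minimizes mean squared
reconstruction error with Adam. The latent vector is used either alone
(mode "latent_only", Experiment A) or concatenated to the original pair
embedding (mode "original_plus_latent", Experiment B) as classifier input.

Hidden widths taper linearly between the input width and the latent width
(fractions 1/4 and 5/8 of the gap), giving 128 -> 112 -> 88 -> 64 for the
default latent size 64.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .embedding import EmbeddingTable, embed_pairs
from .negatives import LabeledPairSet

logger = logging.getLogger("mirlink")

DEFAULT_LATENT_DIM = 64
DEFAULT_AE_EPOCHS = 200
DEFAULT_AE_BATCH = 128
DEFAULT_AE_LR = 1e-3
DEFAULT_AE_SPLIT = 0.9

FeatureMode = Literal["latent_only", "original_plus_latent"]


def hidden_widths(input_dim: int, latent_dim: int) -> tuple[int, int]:
    """Linear taper: h1/h2 at 1/4 and 5/8 of the input->latent gap."""
    gap = input_dim - latent_dim
    h1 = round(input_dim - 0.25 * gap)
    h2 = round(input_dim - 0.625 * gap)
    return max(h1, latent_dim, 1), max(h2, latent_dim, 1)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    """Minimal Adam optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class MinMaxScaling:
    """Per-dimension min/max fit on AE training rows; maps onto [0,1]."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaling":
        return cls(X.min(axis=0), X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        span = np.where(span == 0, 1.0, span)
        return np.clip((X - self.mins) / span, 0.0, 1.0)


@dataclass
class AutoencoderModel:
    """Trained encoder/decoder weights plus the scaling fit alongside them."""

    encoder_weights: list[np.ndarray]
    encoder_biases: list[np.ndarray]
    decoder_weights: list[np.ndarray]
    decoder_biases: list[np.ndarray]
    latent_dim: int
    input_dim: int
    scaling: MinMaxScaling
    config: dict = field(default_factory=dict)

    def encode(self, X: np.ndarray, *, scaled: bool = False) -> np.ndarray:
        """Latent vectors z = sigma(W3 sigma(W2 sigma(W1 x + b1) + b2) + b3).

        Rows are min-max scaled with the model's stored scaling unless
        `scaled=True`. Output entries are >= 0 (ReLU latent).
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected input dimension {self.input_dim}, got {X.shape[1]}"
            )
        h = X if scaled else self.scaling.transform(X)
        for W, b in zip(self.encoder_weights, self.encoder_biases):
            h = _relu(h @ W + b)
        return h

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Reconstruction in [0,1]^input_dim (sigmoid output layer)."""
        h = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        n_layers = len(self.decoder_weights)
        for li, (W, b) in enumerate(zip(self.decoder_weights, self.decoder_biases)):
            pre = h @ W + b
            h = _sigmoid(pre) if li == n_layers - 1 else _relu(pre)
        return h

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))


def train_autoencoder(
    X: np.ndarray,
    latent_dim: int = DEFAULT_LATENT_DIM,
    epochs: int = DEFAULT_AE_EPOCHS,
    batch: int = DEFAULT_AE_BATCH,
    lr: float = DEFAULT_AE_LR,
    split: float = DEFAULT_AE_SPLIT,
    seed: int = 0,
    allow_expansion: bool = False,
) -> tuple[AutoencoderModel, dict[str, list[float]]]:
    """Train the autoencoder on raw (unscaled) pair-embedding rows.

    Scaling to [0,1] is fit on the training partition of the given rows and
    stored in the model. Rows are split `split`:(1-split) into train/test;
    per-epoch train and test MSE are returned as the loss history.
    Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d array with >= 2 rows")
    input_dim = X.shape[1]
    if latent_dim >= input_dim:
        if not allow_expansion:
            raise ValueError(
                f"latent_dim {latent_dim} >= input dim {input_dim} breaks the "
                "compression contract; pass allow_expansion=True to override"
            )
        warnings.warn(
            f"latent_dim {latent_dim} >= input dim {input_dim}: "
            "autoencoder is not compressing", stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.shape[0])
    n_train = max(1, int(round(split * X.shape[0])))
    if n_train == X.shape[0] and X.shape[0] > 1:
        n_train -= 1
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    scaling = MinMaxScaling.fit(X[train_idx])
    Xtr = scaling.transform(X[train_idx])
    Xte = scaling.transform(X[test_idx])

    h1, h2 = hidden_widths(input_dim, latent_dim)
    dims_enc = [input_dim, h1, h2, latent_dim]
    dims_dec = [latent_dim, h2, h1, input_dim]

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    # small positive bias keeps ReLU units alive at init (guards against a
    # dead latent bottleneck, which freezes the whole encoder)
    We = [glorot(a, b) for a, b in zip(dims_enc[:-1], dims_enc[1:])]
    be = [np.full(b, 0.1) for b in dims_enc[1:]]
    Wd = [glorot(a, b) for a, b in zip(dims_dec[:-1], dims_dec[1:])]
    bd = [np.full(b, 0.1) if i < len(dims_dec) - 2 else np.zeros(b)
          for i, b in enumerate(dims_dec[1:])]
    params = We + be + Wd + bd
    opt = _Adam(params, lr)

    history: dict[str, list[float]] = {"train_mse": [], "test_mse": []}
    n = Xtr.shape[0]
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            xb = Xtr[order[start : start + batch]]
            grads = _ae_backward(xb, We, be, Wd, bd)
            opt.step(grads)
        model = AutoencoderModel(We, be, Wd, bd, latent_dim, input_dim, scaling)
        train_mse = float(np.mean((model.decode(model.encode(Xtr, scaled=True)) - Xtr) ** 2))
        if Xte.shape[0]:
            test_mse = float(np.mean((model.decode(model.encode(Xte, scaled=True)) - Xte) ** 2))
        else:
            test_mse = float("nan")
        history["train_mse"].append(train_mse)
        history["test_mse"].append(test_mse)

    model = AutoencoderModel(
        We, be, Wd, bd, latent_dim, input_dim, scaling,
        config={
            "epochs": epochs, "batch": batch, "lr": lr,
            "split": split, "seed": seed,
        },
    )
    return model, history


def _ae_backward(
    x: np.ndarray,
    We: list[np.ndarray], be: list[np.ndarray],
    Wd: list[np.ndarray], bd: list[np.ndarray],
) -> list[np.ndarray]:
    """Gradients of mean squared reconstruction error, in param order."""
    acts = [x]
    h = x
    for W, b in zip(We, be):
        h = _relu(h @ W + b)
        acts.append(h)
    n_dec = len(Wd)
    for li, (W, b) in enumerate(zip(Wd, bd)):
        pre = h @ W + b
        h = _sigmoid(pre) if li == n_dec - 1 else _relu(pre)
        acts.append(h)

    m = x.shape[0]
    xhat = acts[-1]
    delta = (2.0 / (m * x.shape[1])) * (xhat - x)
    delta = delta * xhat * (1.0 - xhat)                  # sigmoid output

    gWd = [np.empty(0)] * n_dec
    gbd = [np.empty(0)] * n_dec
    n_enc = len(We)
    for li in range(n_dec - 1, -1, -1):
        a_in = acts[n_enc + li]
        gWd[li] = a_in.T @ delta
        gbd[li] = delta.sum(axis=0)
        delta = delta @ Wd[li].T
        if li > 0:
            delta = delta * _relu_grad(acts[n_enc + li])
    gWe = [np.empty(0)] * n_enc
    gbe = [np.empty(0)] * n_enc
    for li in range(n_enc - 1, -1, -1):
        delta = delta * _relu_grad(acts[li + 1])
        gWe[li] = acts[li].T @ delta
        gbe[li] = delta.sum(axis=0)
        if li > 0:
            delta = delta @ We[li].T
    return gWe + gbe + gWd + gbd


def _relu_grad(act: np.ndarray) -> np.ndarray:
    # leaky derivative on an exact-ReLU forward: dead units keep a small
    # gradient path and can recover instead of freezing the encoder
    return np.where(act > 0, 1.0, 0.01)


def build_features(
    pairs: LabeledPairSet | Sequence[tuple[str, str]],
    table: EmbeddingTable,
    model: AutoencoderModel,
    mode: FeatureMode = "original_plus_latent",
) -> np.ndarray:
    """Classifier input rows aligned with pair order.

    Mode "latent_only": rows are the latent vectors z. Mode
    "original_plus_latent": rows are [original 128-d embedding || z].
    """
    if isinstance(pairs, LabeledPairSet):
        keys = [(m, g) for m, g, _ in pairs.pairs]
    else:
        keys = [(m, g) for m, g in pairs]
    X = embed_pairs(table, keys)
    return augment_features(X, model, mode)


def augment_features(
    X: np.ndarray, model: AutoencoderModel, mode: FeatureMode
) -> np.ndarray:
    """Apply the trained encoder to raw pair-embedding rows."""
    Z = model.encode(X)
    if mode == "latent_only":
        out = Z
    elif mode == "original_plus_latent":
        out = np.hstack([X, Z])
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite entries in feature matrix")
    return out
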