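"""Compact deterministic feed-forward network primitives.

A small dense network (linear layers + rectifier hiddens + sigmoid output)
with inverted dropout, binary cross-entropy loss and Adam updates, all in
numpy. Every stochastic element (weight init, minibatch order, dropout
masks) draws from a single seeded Generator, so training is bit-for-bit
reproducible for a given seed and BLAS configuration.

The rectifier hiddens are load-bearing: the attribution module's Rescale
rule is defined for piecewise-linear activations.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adaptive-moment estimator over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class DenseNet:
    """Fully connected net: input -> hidden widths (ReLU) -> 1 logit."""

    def __init__(self, n_input: int, hidden: tuple[int, ...], rng: np.random.Generator):
        widths = [n_input, *hidden, 1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for rectifier layers
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.widths = widths

    @property
    def n_input(self) -> int:
        return self.widths[0]

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Logits plus caches for backprop.

        With ``dropout > 0`` and an rng, inverted dropout is applied to
        each hidden activation (training mode).
        """
        A = np.asarray(X, dtype=np.float64)
        caches = []
        n_layers = len(self.W)
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            Z = A @ W + b
            if li < n_layers - 1:
                H = np.maximum(Z, 0.0)
                mask = None
                if dropout > 0.0 and rng is not None:
                    mask = (rng.random(H.shape) >= dropout) / (1.0 - dropout)
                    H = H * mask
                caches.append((A, Z, mask))
                A = H
            else:
                caches.append((A, Z, None))
        logits = Z[:, 0]
        return logits, caches

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(X))

    # -- backward -----------------------------------------------------------

    def backward(self, caches, dlogits: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(logits)."""
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        dZ = dlogits[:, None]
        for li in range(len(self.W) - 1, -1, -1):
            A_in, Z, _mask = caches[li]
            gW[li] = A_in.T @ dZ
            gb[li] = dZ.sum(axis=0)
            if li > 0:
                dA = dZ @ self.W[li].T
                _, Z_prev, mask_prev = caches[li - 1]
                if mask_prev is not None:
                    dA = dA * mask_prev
                dZ = dA * (Z_prev > 0)
        return [*gW, *gb]


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on sigmoid(logits) and its logit-gradient."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    grad = (p - y) / len(y)
    return loss, grad


def train_dense(
    net: DenseNet,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    dropout: float,
    rng: np.random.Generator,
) -> list[float]:
    """Minibatch Adam training; returns the per-epoch mean training loss."""
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    opt = Adam(net.params, lr=lr)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            logits, caches = net.forward(X[idx], dropout=dropout, rng=rng)
            loss, dlogits = bce_loss_and_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training aborted: non-finite loss at step {opt.t} "
                    f"(lr={lr}, batch={batch_size})"
                )
            grads = net.backward(caches, dlogits)
            opt.step(net.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
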