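"""Minimal feed-forward neural network internals.

Dense numpy implementation of the two-hidden-layer rectifier network used
by the learning blocks, with inverted dropout, a softmax or sigmoid head,
full-batch Adam, and manual backpropagation.  Everything is seeded through
``numpy.random.Generator``, so training is bit-reproducible on a given
platform.  Kept private: the public surface is the estimator classes.
"""

from __future__ import annotations

import numpy as np


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def stable_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / np.sum(ez, axis=axis, keepdims=True)


class Adam:
    """Adam with bias correction over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / b1c
            vhat = self.v[key] / b2c
            self.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def init_block(rng: np.random.Generator, d: int, hidden_sizes: tuple[int, int]) -> dict:
    """He-normal weights for the d -> h1 -> h2 rectifier trunk."""
    h1, h2 = hidden_sizes
    return {
        "W1": rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h1)),
        "b1": np.zeros(h1),
        "W2": rng.normal(0.0, np.sqrt(2.0 / h1), size=(h1, h2)),
        "b2": np.zeros(h2),
    }


def init_softmax_head(rng: np.random.Generator, h2: int, n_classes: int = 2) -> dict:
    return {
        "W3": rng.normal(0.0, np.sqrt(1.0 / h2), size=(h2, n_classes)),
        "b3": np.zeros(n_classes),
    }


def block_forward(params: dict, X: np.ndarray, dropout: float,
                  rng: np.random.Generator | None, train: bool) -> tuple[np.ndarray, dict]:
    """Hidden representation (post-rectifier, inverted dropout in training).

    Returns the (possibly dropped) h2-wide activation and the cache needed
    for backprop.  Dropout sits after both hidden layers.
    """
    Z1 = X @ params["W1"] + params["b1"]
    A1 = relu(Z1)
    if train and dropout > 0.0:
        mask1 = (rng.random(A1.shape) >= dropout) / (1.0 - dropout)
        A1d = A1 * mask1
    else:
        mask1 = None
        A1d = A1
    Z2 = A1d @ params["W2"] + params["b2"]
    A2 = relu(Z2)
    if train and dropout > 0.0:
        mask2 = (rng.random(A2.shape) >= dropout) / (1.0 - dropout)
        A2d = A2 * mask2
    else:
        mask2 = None
        A2d = A2
    cache = {"X": X, "Z1": Z1, "A1d": A1d, "Z2": Z2, "mask1": mask1, "mask2": mask2}
    return A2d, cache


def block_backward(params: dict, cache: dict, dA2d: np.ndarray) -> dict:
    """Gradients of the trunk parameters given the hidden-output gradient."""
    if cache["mask2"] is not None:
        dA2 = dA2d * cache["mask2"]
    else:
        dA2 = dA2d
    dZ2 = dA2 * (cache["Z2"] > 0)
    grads = {
        "W2": cache["A1d"].T @ dZ2,
        "b2": dZ2.sum(axis=0),
    }
    dA1d = dZ2 @ params["W2"].T
    if cache["mask1"] is not None:
        dA1 = dA1d * cache["mask1"]
    else:
        dA1 = dA1d
    dZ1 = dA1 * (cache["Z1"] > 0)
    grads["W1"] = cache["X"].T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    return grads


def softmax_head_loss(params: dict, hidden: np.ndarray, y: np.ndarray,
                      eps: float = 1e-12) -> tuple[float, np.ndarray, dict]:
    """Mean two-class cross-entropy; returns loss, dHidden, head grads."""
    n = hidden.shape[0]
    logits = hidden @ params["W3"] + params["b3"]
    probs = stable_softmax(logits, axis=1)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads = {"W3": hidden.T @ dlogits, "b3": dlogits.sum(axis=0)}
    dhidden = dlogits @ params["W3"].T
    return loss, dhidden, grads
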