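"""Sequential container, softmax cross-entropy loss, Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Sequential", "Adam", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    return z


class Sequential:
    """A stack of layers mapping (B,16) token indices to (B,16,C) logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator) -> float:
        """Mean categorical cross-entropy over all positions; backprops."""
        logits = self.forward(x, train=True, rng=rng)
        probs = softmax(logits.astype(np.float64))
        n = y.size  # batch * positions
        rows = np.arange(x.shape[0])[:, None]
        cols = np.arange(x.shape[1])[None, :]
        loss = float(-np.log(np.maximum(probs[rows, cols, y], 1e-12)).mean())
        dlogits = probs
        dlogits[rows, cols, y] -= 1.0
        self.backward((dlogits / n).astype(np.float32))
        return loss

    def loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 1024) -> float:
        """Evaluation-mode mean cross-entropy (no dropout, no gradient)."""
        total, count = 0.0, 0
        for s in range(0, x.shape[0], batch_size):
            xb, yb = x[s:s + batch_size], y[s:s + batch_size]
            probs = softmax(self.forward(xb).astype(np.float64))
            rows = np.arange(xb.shape[0])[:, None]
            cols = np.arange(xb.shape[1])[None, :]
            total += float(-np.log(
                np.maximum(probs[rows, cols, yb], 1e-12)).sum())
            count += yb.size
        return total / count

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Row-stochastic (n,16,C) class probabilities, evaluation mode."""
        out = []
        for s in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[s:s + batch_size])
                               .astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict_labels(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Per-position argmax labels (n,16); ties break to lowest index."""
        out = []
        for s in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[s:s + batch_size]).argmax(axis=-1))
        return np.concatenate(out, axis=0)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for l in self.layers for p in l.params.values()]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match model structure")
        for p, w in zip(flat, weights):
            p[...] = w


class Adam:
    """Adam with in-place parameter updates and a mutable learning rate."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._slots = []
        for layer in model.layers:
            for name, p in layer.params.items():
                self._slots.append((layer, name, p,
                                    np.zeros_like(p), np.zeros_like(p)))

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, name, p, m, v in self._slots:
            g = layer.grads[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
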