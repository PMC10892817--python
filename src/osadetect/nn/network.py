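"""Network container, softmax cross-entropy loss, and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from .layers import Layer, Param, Sequential


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A feed-forward stack mapping image batches to class probabilities."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int]):
        self.stack = Sequential(layers)
        self.input_shape = input_shape

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ValidationError(
                f"expected batch of shape (n, {self.input_shape}), got {x.shape}"
            )
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.stack.forward(self._check(x), train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities in evaluation mode (dropout off)."""
        x = self._check(x)
        out = [softmax(self.forward_logits(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   optimizer: "Adam") -> float:
        """One forward/backward/update step; returns the mean CE loss."""
        logits = self.forward_logits(x, train=True)
        probs = softmax(logits.astype(np.float64))
        n = len(x)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        self.stack.backward(grad.astype(logits.dtype))
        optimizer.step(self.params())
        return loss

    def params(self) -> list[Param]:
        return self.stack.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValidationError("learning rate must be positive")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, params: list[Param]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in params:
            st = p.state
            if "m" not in st:
                st["m"] = np.zeros_like(p.value)
                st["v"] = np.zeros_like(p.value)
            st["m"] = b1 * st["m"] + (1 - b1) * p.grad
            st["v"] = b2 * st["v"] + (1 - b2) * p.grad ** 2
            m_hat = st["m"] / (1 - b1 ** self.t)
            v_hat = st["v"] / (1 - b2 ** self.t)
            p.value -= (self.lr * m_hat /
                        (np.sqrt(v_hat) + self.eps)).astype(p.value.dtype)
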