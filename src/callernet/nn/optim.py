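"""Optimizers and classification losses."""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter


class Adam:
    """Adam with bias correction; the default optimizer for all trainers."""

    def __init__(self, params: list[Parameter], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(np.float32)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch computed in the log domain.

    Returns (loss, gradient w.r.t. logits). Labels are integer class ids.
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = float(-logp[np.arange(n), labels].mean())
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Classifier(Module):
    """A logits-producing network with a softmax probability head.

    ``forward`` emits class probabilities (rows sum to one); training uses
    ``forward_logits`` with a log-domain loss for numerical stability.
    """

    def __init__(self, net: Module, n_classes: int):
        super().__init__()
        self.net = net
        self.n_classes = n_classes

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.net(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(x))

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        return self.net.backward(grad_logits)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward_logits(x).argmax(axis=1)

    def complexity(self, in_shape):
        out_shape, fl = self.net.complexity(in_shape)
        return out_shape, fl + 3.0 * float(np.prod(out_shape))  # softmax head
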