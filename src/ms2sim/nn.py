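"""Minimal dense / 1-D convolutional neural-net primitives on numpy.

Only what the Siamese tower and the embedding evaluator need: fully
connected layers, a same-padded 1-D convolution, elementwise activations and
an Adam optimizer, each with hand-written backward passes.  Everything is
deterministic given the seed used to initialize weights; there are no
stochastic layers, so inference is exactly reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1dSame", "Adam", "relu", "relu_grad", "softplus",
           "softplus_grad"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def softplus(x: np.ndarray) -> np.ndarray:
    # stable log(1 + exp(x))
    return np.logaddexp(0.0, x)


def softplus_grad(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class Dense:
    """Fully connected layer y = x @ W + b with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class Conv1dSame:
    """1-D convolution over a single-channel sequence, 'same' zero padding.

    Input (batch, length) -> output (batch, length, filters).  Implemented
    via a strided sliding-window view plus one matmul, which keeps the
    backward pass a pair of einsums.
    """

    def __init__(self, kernel_size: int, filters: int, rng: np.random.Generator) -> None:
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for symmetric same-padding")
        limit = np.sqrt(6.0 / (kernel_size + filters))
        self.W = rng.uniform(-limit, limit, size=(kernel_size, filters))
        self.b = np.zeros(filters)
        self.kernel_size = kernel_size

    def _windows(self, x: np.ndarray) -> np.ndarray:
        pad = self.kernel_size // 2
        padded = np.pad(x, ((0, 0), (pad, pad)))
        return np.lib.stride_tricks.sliding_window_view(
            padded, self.kernel_size, axis=1
        )  # (batch, length, kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = self._windows(x)
        self._length = x.shape[1]
        return self._win @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # dy: (batch, length, filters)
        self.dW = np.einsum("blk,blf->kf", self._win, dy)
        self.db = dy.sum(axis=(0, 1))
        dwin = np.einsum("blf,kf->blk", dy, self.W)
        pad = self.kernel_size // 2
        dx_padded = np.zeros((dy.shape[0], self._length + 2 * pad))
        for k in range(self.kernel_size):
            dx_padded[:, k : k + self._length] += dwin[:, :, k]
        return dx_padded[:, pad : pad + self._length]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Adam:
    """Adam optimizer updating a flat list of parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay and p.ndim > 1:  # decoupled decay; biases exempt
                p *= 1.0 - self.lr * self.weight_decay
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
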