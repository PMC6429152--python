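"""Minimal seeded neural-network engine (numpy, CPU, reverse-mode by hand).

Implements exactly the pieces the interaction models need: dense and 1-D
convolution layers, max pooling, batch normalization, ReLU, inverted
dropout, a softmax/cross-entropy head, and Adam/SGD optimizers.  All layers
expose ``forward(x, training)`` / ``backward(grad)`` and collect parameters
and gradients for the optimizer; initialization and dropout draw from a
``numpy.random.Generator`` supplied by the caller, so builds are fully
reproducible under a seed.

Arrays are float32 by default.  Convolution input is laid out ``(N, L, C)``
(batch, length, channels).
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer; stateless layers override ``forward``/``backward`` only."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        """All persistent arrays: parameters plus any non-trained statistics."""
        return self.params()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)  # He initialization (ReLU networks)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Conv1D(Layer):
    """Same-padding 1-D convolution over (N, L, C_in) -> (N, L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = (rng.standard_normal((kernel, c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2

    def forward(self, x, training):
        n, length, c_in = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp = xp
        self._shape = (n, length, c_in)
        if c_in == 1:
            # single channel: one im2col matmul (N*L, K) @ (K, C_out)
            cols = np.lib.stride_tricks.sliding_window_view(
                xp[:, :, 0], self.kernel, axis=1).reshape(n * length, self.kernel)
            self._cols = cols
            y = cols @ self.W[:, 0, :] + self.b
            return y.reshape(n, length, -1)
        # multichannel: sum of shifted matmuls avoids the im2col copy
        y = np.empty((n, length, self.W.shape[2]), dtype=x.dtype)
        y[...] = self.b
        for k in range(self.kernel):
            y += xp[:, k:k + length, :] @ self.W[k]
        return y

    def backward(self, grad):
        n, length, c_in = self._shape
        if c_in == 1:
            g2 = grad.reshape(n * length, -1)
            self.dW[...] = (self._cols.T @ g2)[:, None, :]
            self.db[...] = g2.sum(axis=0)
        else:
            gf = grad.reshape(n * length, -1)
            for k in range(self.kernel):
                xk = self._xp[:, k:k + length, :].reshape(n * length, c_in)
                self.dW[k] = xk.T @ gf
            self.db[...] = gf.sum(axis=0)
        dxp = np.zeros((n, length + self.kernel - 1, c_in), dtype=grad.dtype)
        for k in range(self.kernel):  # scatter-add per kernel offset
            dxp[:, k:k + length, :] += grad @ self.W[k].T
        return dxp[:, self.pad_left:self.pad_left + length, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPool1D(Layer):
    """Non-overlapping max pool; a trailing remainder shorter than ``size`` is dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training):
        n, length, c = x.shape
        m = length // self.size
        self._in_shape = x.shape
        xr = x[:, :m * self.size, :].reshape(n, m, self.size, c)
        if self.size == 2:  # comparison mask beats strided argmax
            self._mask2 = xr[:, :, 0, :] >= xr[:, :, 1, :]
            return np.where(self._mask2, xr[:, :, 0, :], xr[:, :, 1, :])
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        n, length, c = self._in_shape
        m = length // self.size
        dxr = np.zeros((n, m, self.size, c), dtype=grad.dtype)
        if self.size == 2:
            dxr[:, :, 0, :] = np.where(self._mask2, grad, 0)
            dxr[:, :, 1, :] = np.where(self._mask2, 0, grad)
        else:
            n_idx, m_idx, c_idx = np.ogrid[:n, :m, :c]
            dxr[n_idx, m_idx, self._argmax, c_idx] = grad
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :m * self.size, :] = dxr.reshape(n, m * self.size, c)
        return dx


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics for inference.

    Normalizes the last axis; for conv inputs (N, L, C) statistics pool over
    batch and length.  Inference statistics are a bias-corrected exponential
    moving average of the batch statistics (correction factor 1 - m^t), so
    they are meaningful even after very few update steps.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=dtype)  # raw EMA
        self.running_var = np.zeros(n_features, dtype=dtype)   # raw EMA
        self.n_updates = np.zeros(1)
        self.momentum = momentum
        self.eps = eps

    def _inference_stats(self):
        t = float(self.n_updates[0])
        if t == 0:
            return np.zeros_like(self.running_mean), np.ones_like(self.running_var)
        correction = 1.0 - self.momentum ** t
        return self.running_mean / correction, self.running_var / correction

    def forward(self, x, training):
        flat = x.reshape(-1, x.shape[-1])
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
            self.n_updates += 1
            self._flat, self._mean = flat, mean
        else:
            mean, var = self._inference_stats()
        self._istd = 1.0 / np.sqrt(var + self.eps)
        # fused affine: out = xhat*gamma + beta = flat*a + c (xhat built lazily)
        a = self.gamma * self._istd
        c = self.beta - mean * a
        self._shape = x.shape
        return (flat * a + c).reshape(x.shape)

    def backward(self, grad):
        g = grad.reshape(-1, grad.shape[-1])
        m = g.shape[0]
        xhat = (self._flat - self._mean) * self._istd
        self.dgamma[...] = (g * xhat).sum(axis=0)
        self.dbeta[...] = g.sum(axis=0)
        dxhat = g * self.gamma
        dx = (self._istd / m) * (m * dxhat - dxhat.sum(axis=0)
                                 - xhat * (dxhat * xhat).sum(axis=0))
        return dx.reshape(self._shape).astype(grad.dtype)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var,
                self.n_updates]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state(self):
        return [s for layer in self.layers for s in layer.state()]


class PairNet(Layer):
    """Two parallel branches (RNA, protein) concatenated into one head.

    ``forward`` takes a tuple ``(x_rna, x_protein)``; ``backward`` returns the
    matching gradient tuple.
    """

    def __init__(self, branch_rna: Sequential, branch_protein: Sequential,
                 head: Sequential):
        self.branch_rna = branch_rna
        self.branch_protein = branch_protein
        self.head = head

    def forward(self, x, training):
        xr, xp = x
        hr = self.branch_rna.forward(xr, training)
        hp = self.branch_protein.forward(xp, training)
        self._split = hr.shape[1]
        return self.head.forward(np.concatenate([hr, hp], axis=1), training)

    def backward(self, grad):
        g = self.head.backward(grad)
        gr = self.branch_rna.backward(g[:, :self._split])
        gp = self.branch_protein.backward(g[:, self._split:])
        return (gr, gp)

    def params(self):
        return (self.branch_rna.params() + self.branch_protein.params()
                + self.head.params())

    def grads(self):
        return (self.branch_rna.grads() + self.branch_protein.grads()
                + self.head.grads())

    def state(self):
        return (self.branch_rna.state() + self.branch_protein.state()
                + self.head.state())


# ---------------------------------------------------------------------------
# Loss and optimizers
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of softmax outputs against integer labels."""
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean())


def softmax_cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. logits for the fused softmax/cross-entropy head."""
    probs = softmax(logits)
    loss = cross_entropy(probs, labels)
    grad = probs.copy()
    grad[np.arange(len(labels)), labels] -= 1.0
    return loss, (grad / len(labels)).astype(logits.dtype)


class Optimizer:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.params, self.grad_bufs, self.lr = params, grads, lr

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    def step(self):
        for p, g in zip(self.params, self.grad_bufs):
            p -= (self.lr * g).astype(p.dtype)


class Adam(Optimizer):
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, grads, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_bufs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g, dtype=np.float64)
            update = (self.lr * (m / bias1)
                      / (np.sqrt(v / bias2) + self.eps))
            p -= update.astype(p.dtype)


def snapshot_params(net: Layer) -> list[np.ndarray]:
    """Copy of the full persistent state (incl. batch-norm running stats)."""
    return [p.copy() for p in net.state()]


def restore_params(net: Layer, snapshot: list[np.ndarray]) -> None:
    for p, s in zip(net.state(), snapshot):
        p[...] = s
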