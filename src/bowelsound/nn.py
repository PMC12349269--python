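"""Minimal neural-network layers on numpy with hand-written backprop.

Just the pieces the bowel-sound classifier needs: dense and same-padded
1-D convolution layers, layer normalization, ReLU, inverted dropout,
scaled dot-product multi-head self-attention, sinusoidal positional
encoding, global average pooling, and a numerically stable
sigmoid/binary-cross-entropy head, plus an Adam optimizer.

Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``; parameter gradients
accumulate in ``grads``. Correctness of each backward pass is pinned by
finite-difference checks in the test suite.

Sequence tensors are (batch, time, channels) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv1DSame",
    "LayerNorm",
    "ReLU",
    "Dropout",
    "PositionalEncoding",
    "MultiHeadSelfAttention",
    "GlobalAveragePool",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base class: parameter container plus forward/backward contract."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())


class Dense(Layer):
    """Affine map on the last axis: y = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _uniform_fan_in(rng, d_in, (d_in, d_out)),
            "b": _uniform_fan_in(rng, d_in, (d_out,)),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.grads["W"] += x2.T @ g2
        self.grads["b"] += g2.sum(axis=0)
        return grad @ self.params["W"].T


class Conv1DSame(Layer):
    """1-D convolution over the time axis with same-length zero padding.

    Kernel shape (k, c_in, c_out); odd k required so output frame t sees
    input frames t - k//2 .. t + k//2.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("same-padded conv requires an odd kernel size")
        self.kernel = kernel
        fan_in = kernel * c_in
        self.params = {
            "W": _uniform_fan_in(rng, fan_in, (kernel, c_in, c_out)),
            "b": _uniform_fan_in(rng, fan_in, (c_out,)),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._xp = xp
        T = x.shape[1]
        out = np.zeros((x.shape[0], T, self.params["W"].shape[2]))
        for k in range(self.kernel):
            out += xp[:, k : k + T, :] @ self.params["W"][k]
        return out + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        T = grad.shape[1]
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            self.grads["W"][k] += np.tensordot(
                self._xp[:, k : k + T, :], grad, axes=([0, 1], [0, 1])
            )
            dxp[:, k : k + T, :] += grad @ self.params["W"][k].T
        self.grads["b"] += grad.sum(axis=(0, 1))
        return dxp[:, pad : pad + T, :]


class LayerNorm(Layer):
    """Normalization over the channel axis with learned gain and bias."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(d), "beta": np.zeros(d)}
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.grads["gamma"] += (grad * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.grads["beta"] += grad.reshape(-1, grad.shape[-1]).sum(axis=0)
        dxhat = grad * self.params["gamma"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) * inv_std


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class PositionalEncoding(Layer):
    """Additive fixed sinusoidal position code (no learned parameters)."""

    def __init__(self, max_len: int, d_model: int):
        super().__init__()
        pos = np.arange(max_len)[:, None]
        i = np.arange(d_model)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
        pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        self.pe = pe  # (max_len, d_model)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x + self.pe[: x.shape[1]]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with h parallel heads.

    Per head, weights = softmax(Q K^T / sqrt(d_k)) row-wise and the output
    is weights V; heads are concatenated and linearly mixed. d_k = d/h.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.h = n_heads
        self.d_k = d_model // n_heads
        self.params = {}
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self.params[name] = _uniform_fan_in(rng, d_model, (d_model, d_model))
            self.params[name[0] + "b" + name[1]] = _uniform_fan_in(
                rng, d_model, (d_model,)
            )
        self.zero_grad()

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        return x.reshape(B, T, self.h, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, d_k = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * d_k)

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """(B, h, T, T) softmax weights for input x (inference helper)."""
        p = self.params
        Q = self._split(x @ p["Wq"] + p["Wbq"])
        K = self._split(x @ p["Wk"] + p["Wbk"])
        return _softmax_last(Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.d_k))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.params
        self._x = x
        self._Q = self._split(x @ p["Wq"] + p["Wbq"])
        self._K = self._split(x @ p["Wk"] + p["Wbk"])
        self._V = self._split(x @ p["Wv"] + p["Wbv"])
        scores = self._Q @ self._K.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        self._A = _softmax_last(scores)
        self._O = self._merge(self._A @ self._V)  # (B, T, D)
        return self._O @ p["Wo"] + p["Wbo"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self.params
        B, T, D = grad.shape
        O2 = self._O.reshape(-1, D)
        g2 = grad.reshape(-1, D)
        self.grads["Wo"] += O2.T @ g2
        self.grads["Wbo"] += g2.sum(axis=0)
        dO = self._split(grad @ p["Wo"].T)  # (B, h, T, d_k)

        dA = dO @ self._V.transpose(0, 1, 3, 2)
        dV = self._A.transpose(0, 1, 3, 2) @ dO
        # softmax Jacobian applied row-wise
        dS = self._A * (dA - (dA * self._A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.d_k)
        dQ = dS @ self._K
        dK = dS.transpose(0, 1, 3, 2) @ self._Q

        x2 = self._x.reshape(-1, D)
        dx = np.zeros_like(self._x)
        for name, d_split in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            d_flat = self._merge(d_split)
            d2 = d_flat.reshape(-1, D)
            self.grads[name] += x2.T @ d2
            self.grads[name[0] + "b" + name[1]] += d2.sum(axis=0)
            dx += d_flat @ p[name].T
        return dx


class GlobalAveragePool(Layer):
    """Mean over the time axis: (B, T, D) -> (B, D)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._T, axis=1) / self._T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits).

    Uses the log-sum-exp form log(1 + e^z) - y z, stable for large |z|.
    """
    z = logits.astype(np.float64)
    y = y.astype(np.float64)
    softplus = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
    loss = float(np.mean(softplus - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


class Adam:
    """Adam with bias correction; operates on a {name: array} parameter view."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, p in params.items():
            g = grads[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
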