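"""Minimal NumPy neural-network layers for the SE-FCN.

All feature maps use the layout ``(batch N, rows H, time W, filters C)``:
electrode rows are the spatial height, time is the width, and learned
filters form the channel depth.  Every convolution in this network has a
kernel of (1, k) acting along time only, so convolutions are implemented
as strided 1-D operations broadcast over rows; electrode rows share
weights but never mix until the dense head.

Layers implement ``forward(x, train)`` / ``backward(grad)`` and expose
``params`` / ``grads`` dicts consumed by :class:`Adam`.  Gradient
correctness of every layer is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ConvTime(Layer):
    """2-D convolution with kernel (1, k) and stride (1, s) along time.

    With k=4, s=2, pad=1 the time axis is halved exactly; with k=1, s=1,
    pad=0 this is a pointwise (1x1) score layer.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = {
            "W": _he_init(rng, (kernel, c_in, c_out), kernel * c_in),
            "b": np.zeros(c_out),
        }

    def out_width(self, w: int) -> int:
        return (w + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (0, 0)))
        self._in_shape = x.shape
        wout = self.out_width(x.shape[2])
        W = self.params["W"]
        c_in, c_out = W.shape[1], W.shape[2]
        # im2col: one gather then a single GEMM (BLAS does the heavy lifting)
        win = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=2)
        win = win[:, :, ::s, :, :][:, :, :wout]  # (N, H, Wout, Cin, k)
        cols = np.ascontiguousarray(np.moveaxis(win, 4, 3)).reshape(-1, k * c_in)
        self._cols = cols
        out = cols @ W.reshape(k * c_in, c_out)
        return out.reshape(x.shape[0], x.shape[1], wout, c_out) + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        W = self.params["W"]
        c_in, c_out = W.shape[1], W.shape[2]
        n, h, w_in, _ = self._in_shape
        wout = grad.shape[2]
        gmat = grad.reshape(-1, c_out)
        dW = (self._cols.T @ gmat).reshape(k, c_in, c_out)
        dcols = (gmat @ W.reshape(k * c_in, c_out).T).reshape(n, h, wout, k, c_in)
        dxpad = np.zeros((n, h, w_in + 2 * p, c_in), dtype=grad.dtype)
        for kk in range(k):
            dxpad[:, :, kk : kk + s * wout : s, :] += dcols[:, :, :, kk, :]
        self.grads = {"W": dW, "b": grad.sum(axis=(0, 1, 2))}
        return dxpad[:, :, p : p + w_in, :]


class ConvTransposeTime(Layer):
    """Transposed convolution along time: kernel (1, k), stride (1, s).

    The adjoint of :class:`ConvTime`; with k=4, s=2, pad=1 the output
    width is exactly twice the input width, the contract the upsampling
    stack relies on.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = {
            "W": _he_init(rng, (kernel, c_in, c_out), kernel * c_in),
            "b": np.zeros(c_out),
        }

    def out_width(self, w: int) -> int:
        return (w - 1) * self.stride - 2 * self.pad + self.kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        self._x = x
        n, h, w, _ = x.shape
        W = self.params["W"]
        full = np.zeros((n, h, (w - 1) * s + k, W.shape[2]), dtype=x.dtype)
        for kk in range(k):
            full[:, :, kk : kk + s * w : s, :] += np.tensordot(
                x, W[kk], axes=([3], [0])
            )
        return full[:, :, p : p + self.out_width(w), :] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        x = self._x
        n, h, w, _ = x.shape
        W = self.params["W"]
        dfull = np.zeros((n, h, (w - 1) * s + k, W.shape[2]), dtype=grad.dtype)
        dfull[:, :, p : p + grad.shape[2], :] = grad
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for kk in range(k):
            sl = dfull[:, :, kk : kk + s * w : s, :]
            dW[kk] = np.tensordot(x, sl, axes=([0, 1, 2], [0, 1, 2]))
            dx += np.tensordot(sl, W[kk], axes=([3], [1]))
        self.grads = {"W": dW, "b": grad.sum(axis=(0, 1, 2))}
        return dx


class BatchNorm(Layer):
    """Per-filter batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.grads = {
            "gamma": (grad * xhat).sum(axis=(0, 1, 2)),
            "beta": grad.sum(axis=(0, 1, 2)),
        }
        g = grad * self.params["gamma"]
        if not self._train:
            return g / std
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        return (g - g.mean(axis=(0, 1, 2)) - xhat * (g * xhat).mean(axis=(0, 1, 2))) / std


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params = {
            "W": _he_init(rng, (n_in, n_out), n_in),
            "b": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def se_squeeze(U: np.ndarray) -> np.ndarray:
    """Global average pooling per filter channel.

    For a feature map U of shape (..., H, W, C), each channel's descriptor
    is its arithmetic mean over all H x W positions.
    """
    return U.mean(axis=(-3, -2))


def se_excitation(z: np.ndarray, W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Two-layer bottleneck gate: sigmoid(W2 @ relu(W1 @ z)), entries in (0,1).

    ``W1`` is (C/r, C), ``W2`` is (C, C/r); ``z`` may carry a leading batch
    axis.  Biases are intentionally absent, matching the original
    squeeze-and-excitation formulation.
    """
    z = np.asarray(z, dtype=np.float64)
    if W1.shape[1] != z.shape[-1] or W2.shape[1] != W1.shape[0]:
        raise ValueError(
            f"inconsistent SE shapes: z C={z.shape[-1]}, W1 {W1.shape}, W2 {W2.shape}"
        )
    hidden = np.maximum(z @ W1.T, 0.0)
    return sigmoid(hidden @ W2.T)


def se_scale(U: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rescale each filter channel of U by its gate weight s_c."""
    s = np.asarray(s, dtype=np.float64)
    if s.shape[-1] != U.shape[-1]:
        raise ValueError(f"{s.shape[-1]} gates for {U.shape[-1]} channels")
    if s.ndim == 1:
        return U * s
    return U * s[:, None, None, :]


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate with reduction ratio r."""

    def __init__(self, c: int, reduction: int = 8, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        c_mid = max(c // reduction, 1)
        self.params = {
            "W1": _he_init(rng, (c_mid, c), c),
            "W2": _he_init(rng, (c, c_mid), c_mid),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        W1, W2 = self.params["W1"], self.params["W2"]
        self._x = x
        self._z = se_squeeze(x)
        self._hpre = self._z @ W1.T
        self._h = np.maximum(self._hpre, 0.0)
        self._s = sigmoid(self._h @ W2.T)
        return x * self._s[:, None, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        W1, W2 = self.params["W1"], self.params["W2"]
        x, z, h, s = self._x, self._z, self._h, self._s
        n, hh, ww, _ = x.shape
        ds = (grad * x).sum(axis=(1, 2))
        dspre = ds * s * (1 - s)
        dW2 = dspre.T @ h
        dh = dspre @ W2
        dhpre = dh * (self._hpre > 0)
        dW1 = dhpre.T @ z
        dz = dhpre @ W1
        self.grads = {"W1": dW1, "W2": dW2}
        return grad * s[:, None, None, :] + dz[:, None, None, :] / (hh * ww)


class Identity(Layer):
    """Drop-in no-op attention block (ablation of the SE gate)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) cross-entropy and d loss / d logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[labels]
    logp = np.log(probs[np.arange(n), labels] + 1e-12)
    loss = -(w * logp).sum() / w.sum()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return float(loss), grad


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
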