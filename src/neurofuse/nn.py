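"""Minimal seeded NumPy neural-network layers with manual backprop.

Float32 throughout. Only the pieces the classifier needs: stride-1
"same"-padded 2D/1D convolutions (im2col), fully connected layers, ReLU,
inverted dropout, softmax cross-entropy, and Adam. Initialisation is
Kaiming-uniform for convolutions and Xavier-uniform for dense layers,
drawn from an explicit generator so two models built with the same seed
are bitwise identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "Conv1d",
    "Linear",
    "relu",
    "relu_backward",
    "Dropout",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def _im2col2d(x: np.ndarray, k: int) -> np.ndarray:
    """[B,C,H,W] -> [B, H*W, C*k*k] with stride 1 and (k-1)//2 padding."""
    p = (k - 1) // 2
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # view: [B, C, H, W, k, k] -> [B, H, W, C, k, k] -> [B, H*W, C*k*k]
    return np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b, h * w, c * k * k
    )


def _col2im2d(cols: np.ndarray, x_shape, k: int) -> np.ndarray:
    """Adjoint of _im2col2d: scatter-add columns back into the image."""
    p = (k - 1) // 2
    b, c, h, w = x_shape
    xp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(b, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + h, dj : dj + w] += cols[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    return xp[:, :, p : p + h, p : p + w]


class Conv2d:
    """3x3 (or kxk), stride-1, same-padded 2D convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.k = k
        self.weight = Param(kaiming_uniform(rng, (out_ch, in_ch * k * k), fan_in))
        self.bias = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col2d(x, self.k)
        out = cols @ self.weight.value.T + self.bias.value
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(b, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        b, oc, h, w = dout.shape
        dflat = dout.reshape(b, oc, h * w).transpose(0, 2, 1)  # [B, HW, out]
        self.weight.grad += np.einsum("bno,bni->oi", dflat, cols, optimize=True)
        self.bias.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.weight.value
        return _col2im2d(dcols, x_shape, self.k)


def _im2col1d(x: np.ndarray, k: int) -> np.ndarray:
    """[B,C,L] -> [B, L, C*k] with stride 1 and same padding."""
    p = (k - 1) // 2
    b, c, l = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    view = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # [B,C,L,k]
    return np.ascontiguousarray(view.transpose(0, 2, 1, 3)).reshape(b, l, c * k)


def _col2im1d(cols: np.ndarray, x_shape, k: int) -> np.ndarray:
    p = (k - 1) // 2
    b, c, l = x_shape
    xp = np.zeros((b, c, l + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(b, l, c, k)
    for d in range(k):
        xp[:, :, d : d + l] += cols[:, :, :, d].transpose(0, 2, 1)
    return xp[:, :, p : p + l]


class Conv1d:
    """k-tap, stride-1, same-padded temporal convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k
        self.k = k
        self.weight = Param(kaiming_uniform(rng, (out_ch, in_ch * k), fan_in))
        self.bias = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        cols = _im2col1d(x, self.k)
        out = cols @ self.weight.value.T + self.bias.value  # [B, L, out]
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        dflat = dout.transpose(0, 2, 1)  # [B, L, out]
        self.weight.grad += np.einsum("blo,bli->oi", dflat, cols, optimize=True)
        self.bias.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.weight.value
        return _col2im1d(dcols, x_shape, self.k)


class Linear:
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        self.weight = Param(
            xavier_uniform(rng, (out_features, in_features), in_features, out_features)
        )
        self.bias = Param(np.zeros(out_features)) if bias else None
        self._cache = None

    def params(self):
        out = [("weight", self.weight)]
        if self.bias is not None:
            out.append(("bias", self.bias))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += dout.T @ x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


class Dropout:
    """Inverted dropout; masks are drawn from the supplied generator."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, rng: np.random.Generator, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], eps, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class Adam:
    def __init__(
        self,
        params: list[tuple[str, Param]],
        lr: float = 0.005,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(p.value) for name, p in params}
        self.v = {name: np.zeros_like(p.value) for name, p in params}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        # fold both bias corrections into one scalar step size
        alpha = DTYPE(self.lr * np.sqrt(b2t) / b1t)
        eps = DTYPE(self.eps * np.sqrt(b2t))
        for name, p in self.params:
            g = p.grad
            m = self.m[name]
            v = self.v[name]
            m *= DTYPE(self.b1)
            m += DTYPE(1 - self.b1) * g
            v *= DTYPE(self.b2)
            np.multiply(g, g, out=g)
            g *= DTYPE(1 - self.b2)
            v += g
            denom = np.sqrt(v)
            denom += eps
            np.divide(m, denom, out=denom)
            denom *= alpha
            p.value -= denom

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()
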