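"""Minimal CNN engine with explicit backpropagation.

The slide-representation pipeline needs two things from its networks that go
beyond plain prediction: (1) access to the activations of a named internal
convolutional layer, and (2) the gradient of a class objective with respect to
those activations (the quantities the gradient-weighted class-activation
machinery consumes).  The engine below keeps both first-class: every
:class:`Sequential` forward pass caches per-layer outputs, and a backward pass
records the gradient arriving at every layer output, so any layer can serve as
the exposed map stack.

Layers operate on NCHW float arrays.  All parameters are initialised from a
caller-supplied :class:`numpy.random.Generator`, so a model is a pure function
of its architecture and seed.  Gradients of every layer are verified against
central finite differences in the test-suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Sequential",
    "SGD",
    "Adam",
    "bce_with_logits",
    "softmax_cross_entropy",
    "mse_loss",
    "sigmoid",
    "softmax",
    "fit",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Base layer: stateless unless it owns parameters."""

    name: str = ""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def params(self) -> dict:
        return {}

    @property
    def grads(self) -> dict:
        return {}


class Conv2d(Layer):
    """3x3-style 'same' convolution via im2col.

    Stride is fixed at 1; padding defaults to (k-1)//2 which preserves the
    spatial shape for odd kernels.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None, name: str = "",
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.kernel = int(kernel)
        self.pad = (self.kernel - 1) // 2 if pad is None else int(pad)
        self.c_in, self.c_out = int(c_in), int(c_out)
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))  # He init
        self.W = (rng.standard_normal((c_out, c_in, kernel, kernel)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = name or f"conv{c_in}x{c_out}"
        self._cache = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}

    @staticmethod
    def _slice2d(xp: np.ndarray, di: int, dj: int, oh: int, ow: int) -> np.ndarray:
        # (C, N*OH*OW) contiguous view of one kernel offset
        c = xp.shape[1]
        return np.ascontiguousarray(
            xp[:, :, di:di + oh, dj:dj + ow].transpose(1, 0, 2, 3)).reshape(c, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} input channels, got {c}")
        p, k = self.pad, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh, ow = xp.shape[2] - k + 1, xp.shape[3] - k + 1
        # one gemm per kernel offset: avoids materialising the k^2-expanded
        # im2col buffer, which is memory-bound at wide channel counts
        acc = np.zeros((self.c_out, n * oh * ow), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                acc += self.W[:, :, di, dj] @ self._slice2d(xp, di, dj, oh, ow)
        out = acc.reshape(self.c_out, n, oh, ow).transpose(1, 0, 2, 3) \
            + self.b[None, :, None, None]
        self._cache = (xp, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, xshape, oh, ow = self._cache
        n = xshape[0]
        k, p = self.kernel, self.pad
        dflat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(
            self.c_out, n * oh * ow)
        self.db[...] = dflat.sum(axis=1)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xsl = self._slice2d(xp, di, dj, oh, ow)
                self.dW[:, :, di, dj] = dflat @ xsl.T
                dsl = (self.W[:, :, di, dj].T @ dflat).reshape(self.c_in, n, oh, ow)
                dxp[:, :, di:di + oh, dj:dj + ow] += dsl.transpose(1, 0, 2, 3)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class _Pool(Layer):
    """Non-overlapping pooling; trailing rows/cols beyond a multiple of the
    pool size are cropped (Keras-style `valid` pooling)."""

    def __init__(self, pool: int | tuple[int, int], name: str):
        self.ph, self.pw = (pool, pool) if isinstance(pool, int) else pool
        self.name = name
        self._cache = None

    def _blocks(self, x: np.ndarray):
        n, c, h, w = x.shape
        oh, ow = h // self.ph, w // self.pw
        if oh == 0 or ow == 0:
            raise ValueError(f"{self.name}: input {h}x{w} smaller than pool "
                             f"{self.ph}x{self.pw}")
        xc = x[:, :, : oh * self.ph, : ow * self.pw]
        return xc.reshape(n, c, oh, self.ph, ow, self.pw), (n, c, h, w, oh, ow)


class MaxPool2d(_Pool):
    def __init__(self, pool: int | tuple[int, int] = 2, name: str = "maxpool"):
        super().__init__(pool, name)

    def forward(self, x: np.ndarray) -> np.ndarray:
        blocks, dims = self._blocks(x)
        out = blocks.max(axis=(3, 5))
        # ties share gradient equally so backward stays a true subgradient
        mask = blocks == out[:, :, :, None, :, None]
        self._cache = (mask, mask.sum(axis=(3, 5)), dims)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, counts, (n, c, h, w, oh, ow) = self._cache
        scaled = (dout / counts)[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : oh * self.ph, : ow * self.pw] = (mask * scaled).reshape(
            n, c, oh * self.ph, ow * self.pw)
        return dx


class AvgPool2d(_Pool):
    def __init__(self, pool: int | tuple[int, int] = 2, name: str = "avgpool"):
        super().__init__(pool, name)

    def forward(self, x: np.ndarray) -> np.ndarray:
        blocks, dims = self._blocks(x)
        self._cache = dims
        return blocks.mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w, oh, ow = self._cache
        area = self.ph * self.pw
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        spread = np.broadcast_to((dout / area)[:, :, :, None, :, None],
                                 (n, c, oh, self.ph, ow, self.pw))
        dx[:, :, : oh * self.ph, : ow * self.pw] = spread.reshape(
            n, c, oh * self.ph, ow * self.pw)
        return dx


class GlobalAvgPool(Layer):
    def __init__(self, name: str = "gap"):
        self.name = name
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 name: str = "dense", dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = name
        self._x = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential:
    """An ordered layer stack with named-layer introspection.

    After ``backward``, ``output_grads[name]`` holds the gradient of the
    scalar objective with respect to the *output* of the layer called
    ``name`` — the hook used to extract class-activation gradients.
    """

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        self.outputs: dict[str, np.ndarray] = {}
        self.output_grads: dict[str, np.ndarray] = {}

    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def _index(self, name: str) -> int:
        for i, l in enumerate(self.layers):
            if l.name == name:
                return i
        raise KeyError(f"no layer named {name!r}; available: {self.layer_names()}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.outputs = {}
        for layer in self.layers:
            x = layer.forward(x)
            self.outputs[layer.name] = x
        return x

    def forward_from(self, name: str, value: np.ndarray) -> np.ndarray:
        """Re-run the tail of the network with the output of ``name`` replaced.

        Used by finite-difference checks of activation gradients; does not
        disturb cached state needed by ``backward``.
        """
        i = self._index(name)
        x = value
        for layer in self.layers[i + 1:]:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.output_grads = {}
        for layer in reversed(self.layers):
            self.output_grads[layer.name] = dout
            dout = layer.backward(dout)
        return dout

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[tuple[str, str, np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            for key, val in layer.params.items():
                out.append((layer.name, key, val, layer.grads[key]))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{k}": v.copy() for ln, k, v, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for ln, k, v, _ in self.parameters():
            key = f"{ln}.{k}"
            if key not in state:
                raise KeyError(f"missing parameter {key} in state dict")
            if state[key].shape != v.shape:
                raise ValueError(f"shape mismatch for {key}: "
                                 f"{state[key].shape} vs {v.shape}")
            v[...] = state[key]


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class SGD:
    def __init__(self, lr: float = 0.01, momentum: float = 0.9):
        self.lr, self.momentum = lr, momentum
        self._vel: dict[str, np.ndarray] = {}

    def step(self, model: Sequential) -> None:
        for ln, k, p, g in model.parameters():
            key = f"{ln}.{k}"
            v = self._vel.setdefault(key, np.zeros_like(p))
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, model: Sequential) -> None:
        self._t += 1
        for ln, k, p, g in model.parameters():
            key = f"{ln}.{k}"
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self._t)
            vh = v / (1 - self.b2 ** self._t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# losses: each returns (scalar loss, gradient wrt logits)
# ---------------------------------------------------------------------------


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    z = logits.reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = z.size
    # log(1+exp(-|z|)) form is stable for both signs
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / n
    return loss, grad.reshape(logits.shape)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    y = np.asarray(y, dtype=int).reshape(-1)
    p = softmax(logits, axis=1)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def mse_loss(pred: np.ndarray, y: np.ndarray):
    p = pred.reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    diff = p - y
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 * diff / p.size).reshape(pred.shape)


# ---------------------------------------------------------------------------
# generic training loop
# ---------------------------------------------------------------------------


def fit(model: Sequential,
        x: np.ndarray,
        y: np.ndarray,
        loss_fn: Callable,
        optimizer,
        epochs: int,
        batch_size: int | None,
        rng: np.random.Generator,
        shuffle: bool = True,
        callback: Callable[[int, float], None] | None = None) -> list[float]:
    """Mini-batch training; ``batch_size=None`` runs full-batch (needed when
    the loss couples samples, e.g. a partial likelihood over risk sets).

    Returns the per-epoch mean training loss.
    """
    n = x.shape[0]
    bs = n if batch_size is None else int(batch_size)
    history = []
    for epoch in range(int(epochs)):
        order = rng.permutation(n) if (shuffle and bs < n) else np.arange(n)
        total, seen = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            out = model.forward(x[idx])
            loss, dout = loss_fn(out, y[idx])
            model.backward(dout)
            optimizer.step(model)
            total += loss * idx.size
            seen += idx.size
        history.append(total / seen)
        if callback is not None:
            callback(epoch, history[-1])
    return history
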