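"""Minimal 3D convolutional network layers in numpy with explicit backprop.

Everything operates on float32 tensors of shape (B, C, D, H, W).  The scope
is deliberately small — exactly the pieces needed for the volumetric
classifiers in this package: 3D convolution (im2col), ReLU, max/avg pooling,
global average pooling, fully connected heads, residual and densely
connected blocks, softmax cross-entropy, and Adam.  Layers cache what their
backward pass needs; parameters live in ``layer.params`` with matching
gradients in ``layer.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_layers(self) -> list["Layer"]:
        return [self] if self.params else []


class Conv3d(Layer):
    """k^3 'same' convolution (stride 1, zero padding (k-1)//2) via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2
        rng = rng or np.random.default_rng()
        fan_in = c_in * k ** 3
        w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p, k = self.pad, self.k
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        # (B, C, D, H, W, k, k, k) -> (B, D*H*W, C*k^3)
        win = np.moveaxis(win, 1, 4)
        B, D, H, W = win.shape[:4]
        return np.ascontiguousarray(win).reshape(B, D * H * W, -1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, D, H, W = x.shape
        cols = self._im2col(x)
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, (B, C, D, H, W)) if train else None
        return np.moveaxis(out.reshape(B, D, H, W, self.c_out), 4, 1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, (B, C, D, H, W) = self._cache
        k, p = self.k, self.pad
        g2 = np.moveaxis(gout, 1, 4).reshape(B, D * H * W, self.c_out)
        self.grads["W"][...] = np.einsum("bnf,bno->fo", cols, g2,
                                         optimize=True)
        self.grads["b"][...] = g2.sum(axis=(0, 1))
        gcols = g2 @ self.params["W"].T                  # (B, DHW, C*k^3)
        gcols = gcols.reshape(B, D, H, W, C, k, k, k)
        gpad = np.zeros((B, C, D + 2 * p, H + 2 * p, W + 2 * p),
                        dtype=np.float32)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    gpad[:, :, i:i + D, j:j + H, l:l + W] += \
                        np.moveaxis(gcols[..., i, j, l], 4, 1)
        self._cache = None
        if p:
            return gpad[:, :, p:-p, p:-p, p:-p]
        return gpad


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        self._mask = x > 0
        return out

    def backward(self, gout):
        return gout * self._mask


class MaxPool3d(Layer):
    """Non-overlapping f^3 max pooling; spatial dims must be divisible by f."""

    def __init__(self, f: int = 2) -> None:
        super().__init__()
        self.f = f

    def forward(self, x, train=True):
        B, C, D, H, W = x.shape
        f = self.f
        if D % f or H % f or W % f:
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {f}")
        r = x.reshape(B, C, D // f, f, H // f, f, W // f, f)
        out = r.max(axis=(3, 5, 7))
        self._cache = (r, out)
        return out

    def backward(self, gout):
        r, out = self._cache
        mask = r == out[:, :, :, None, :, None, :, None]
        # split gradient equally among ties
        ties = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = mask * (gout[:, :, :, None, :, None, :, None] / ties)
        B, C, Df, f, Hf, _, Wf, _ = r.shape
        return g.reshape(B, C, Df * f, Hf * f, Wf * f)


class AvgPool3d(Layer):
    """Non-overlapping f^3 average pooling."""

    def __init__(self, f: int) -> None:
        super().__init__()
        self.f = f

    def forward(self, x, train=True):
        B, C, D, H, W = x.shape
        f = self.f
        if D % f or H % f or W % f:
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {f}")
        self._in_shape = x.shape
        return x.reshape(B, C, D // f, f, H // f, f, W // f, f) \
                .mean(axis=(3, 5, 7))

    def backward(self, gout):
        f = self.f
        g = gout[:, :, :, None, :, None, :, None] / f ** 3
        g = np.broadcast_to(g, gout.shape[:3] + (f,) + gout.shape[3:4] + (f,)
                            + gout.shape[4:5] + (f,))
        return g.reshape(self._in_shape)


class GlobalAvgPool(Layer):
    """(B, C, D, H, W) -> (B, C)."""

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gout):
        B, C, D, H, W = self._in_shape
        g = gout[:, :, None, None, None] / (D * H * W)
        return np.broadcast_to(g, self._in_shape).copy()


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(n_out, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"][...] = self._x.T @ gout
        self.grads["b"][...] = gout.sum(axis=0)
        return gout @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, gout):
        for lay in reversed(self.layers):
            gout = lay.backward(gout)
        return gout

    def param_layers(self):
        return [pl for lay in self.layers for pl in lay.param_layers()]


class ResidualBlock(Layer):
    """y = relu(x + body(x)); body must preserve shape."""

    def __init__(self, body: Sequential) -> None:
        super().__init__()
        self.body = body
        self._relu = ReLU()

    def forward(self, x, train=True):
        return self._relu.forward(x + self.body.forward(x, train=train),
                                  train=train)

    def backward(self, gout):
        g = self._relu.backward(gout)
        return g + self.body.backward(g)

    def param_layers(self):
        return self.body.param_layers()


class DenseBlock(Layer):
    """Densely connected 3D block: each conv sees the concatenation of the
    block input and all previous layer outputs, and emits ``growth`` new
    channels; the block output is the full concatenation."""

    def __init__(self, c_in: int, n_layers: int, growth: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.convs, self.relus = [], []
        c = c_in
        for _ in range(n_layers):
            self.convs.append(Conv3d(c, growth, k=3, rng=rng))
            self.relus.append(ReLU())
            c += growth
        self.c_out = c

    def forward(self, x, train=True):
        feats = [x]
        for conv, relu in zip(self.convs, self.relus):
            cat = np.concatenate(feats, axis=1)
            feats.append(relu.forward(conv.forward(cat, train=train),
                                      train=train))
        self._widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, gout):
        splits = np.cumsum(self._widths)[:-1]
        grads = [g.copy() for g in np.split(gout, splits, axis=1)]
        for idx in range(len(self.convs) - 1, -1, -1):
            g_in = self.convs[idx].backward(self.relus[idx].backward(grads[idx + 1]))
            w = np.cumsum(self._widths[:idx + 1])[:-1]
            for j, piece in enumerate(np.split(g_in, w, axis=1)):
                grads[j] += piece
        return grads[0]

    def param_layers(self):
        return [pl for c in self.convs for pl in c.param_layers()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a network's parameter layers."""

    def __init__(self, net: Layer, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = net.param_layers()
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                  for lay in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                  for lay in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / corr1) / (np.sqrt(v[k] / corr2) + self.eps)


def get_state(net: Layer) -> list[dict[str, np.ndarray]]:
    return [{k: v.copy() for k, v in lay.params.items()}
            for lay in net.param_layers()]


def set_state(net: Layer, state: list[dict[str, np.ndarray]]) -> None:
    for lay, st in zip(net.param_layers(), state):
        for k in lay.params:
            lay.params[k][...] = st[k]
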