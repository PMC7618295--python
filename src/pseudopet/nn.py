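"""Minimal numpy neural-network layers with hand-written backpropagation.

The package trains only small convolutional models (a slice-wise denoiser
and a displacement-field predictor), so a compact, dependency-free layer
set with explicit forward/backward passes is sufficient and keeps every
training run bitwise-reproducible from a single integer seed.  All layers
are gradient-checked against finite differences in the test suite.

Conventions: activations are float64; images are (batch, channels, *spatial);
each layer caches what its backward pass needs and accumulates parameter
gradients into ``layer.grads`` (zeroed by the optimizer step).
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: parameter dict + matching gradient dict."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def children(self) -> list["Layer"]:
        return []

    def all_layers(self) -> list["Layer"]:
        out = [self]
        for c in self.children():
            out.extend(c.all_layers())
        return out


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        w = (np.zeros((n_in, n_out)) if zero_init
             else _he_init(rng, (n_in, n_out), n_in))
        self.add_param("w", w)
        self.add_param("b", np.zeros(n_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["w"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["w"].T


class SiLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._sig = 1.0 / (1.0 + np.exp(-x))
        return x * self._sig

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self._sig
        return dy * (s + self._x * s * (1 - s))


class ConvNd(Layer):
    """3^d same-padding convolution for d = 2 or 3, stride 1.

    Implemented as a sum of shifted tensor contractions (one per kernel
    offset), which keeps the backward pass a mirror image of the forward.
    """

    def __init__(self, n_dim: int, c_in: int, c_out: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        self.n_dim = n_dim
        k_shape = (c_out, c_in) + (3,) * n_dim
        fan_in = c_in * 3**n_dim
        w = np.zeros(k_shape) if zero_init else _he_init(rng, k_shape, fan_in)
        self.add_param("w", w)
        self.add_param("b", np.zeros(c_out))
        self._offsets = np.stack(
            np.meshgrid(*([np.arange(3)] * n_dim), indexing="ij"), axis=-1
        ).reshape(-1, n_dim)

    def _pad(self, x: np.ndarray) -> np.ndarray:
        pad = [(0, 0), (0, 0)] + [(1, 1)] * self.n_dim
        return np.pad(x, pad)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xp = self._pad(x)
        spatial = x.shape[2:]
        w = self.params["w"]
        out = np.zeros((x.shape[0], w.shape[0], *spatial))
        for off in self._offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            kw = w[(slice(None), slice(None)) + tuple(off)]
            # (B, Ci, *S) x (Co, Ci) -> (B, Co, *S)
            out += np.tensordot(self._xp[sl], kw, axes=([1], [1])).transpose(
                self._to_channel_first(x.ndim)
            )
        return out + self.params["b"].reshape((1, -1) + (1,) * self.n_dim)

    @staticmethod
    def _to_channel_first(ndim: int):
        # tensordot puts the new channel axis last; move it to position 1
        axes = list(range(ndim))
        return [0, ndim - 1] + axes[1:-1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        spatial = dy.shape[2:]
        w = self.params["w"]
        dxp = np.zeros_like(self._xp)
        sum_axes = (0,) + tuple(range(2, dy.ndim))
        self.grads["b"] += dy.sum(axis=sum_axes)
        for off in self._offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            xs = self._xp[sl]
            kidx = (slice(None), slice(None)) + tuple(off)
            # dW[o,c] = sum_{b,*S} dy[b,o,*S] * x[b,c,*S]
            self.grads["w"][kidx] += np.tensordot(
                dy, xs, axes=(sum_axes, sum_axes)
            )
            # dx[b,c,*S] += dy[b,o,*S] * W[o,c]
            dxp[sl] += np.tensordot(dy, w[kidx], axes=([1], [0])).transpose(
                self._to_channel_first(dy.ndim)
            )
        crop = (slice(None), slice(None)) + (slice(1, -1),) * self.n_dim
        return dxp[crop]


class AvgPool(Layer):
    """Factor-2 average pooling over all spatial axes."""

    def __init__(self, n_dim: int):
        super().__init__()
        self.n_dim = n_dim

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        b, c = x.shape[:2]
        spatial = x.shape[2:]
        newshape = [b, c]
        for s in spatial:
            newshape += [s // 2, 2]
        r = x.reshape(newshape)
        axes = tuple(3 + 2 * i for i in range(self.n_dim))
        return r.mean(axis=axes)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        scale = 1.0 / 2**self.n_dim
        out = dy * scale
        for ax in range(2, 2 + self.n_dim):
            out = np.repeat(out, 2, axis=ax)
        return out


class Upsample(Layer):
    """Factor-2 nearest-neighbor upsampling over all spatial axes."""

    def __init__(self, n_dim: int):
        super().__init__()
        self.n_dim = n_dim

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for ax in range(2, 2 + self.n_dim):
            out = np.repeat(out, 2, axis=ax)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c = dy.shape[:2]
        spatial = dy.shape[2:]
        newshape = [b, c]
        for s in spatial:
            newshape += [s // 2, 2]
        r = dy.reshape(newshape)
        axes = tuple(3 + 2 * i for i in range(self.n_dim))
        return r.sum(axis=axes)


class SelfAttention2d(Layer):
    """Single-head global self-attention with a residual connection."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.c = channels
        self.q = Dense(channels, channels, rng)
        self.k = Dense(channels, channels, rng)
        self.v = Dense(channels, channels, rng)
        self.o = Dense(channels, channels, rng, zero_init=True)

    def children(self):
        return [self.q, self.k, self.v, self.o]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._xshape = x.shape
        flat = x.reshape(b, c, h * w).transpose(0, 2, 1)  # (B, N, C)
        self._flat = flat
        q = self.q.forward(flat)
        k = self.k.forward(flat)
        v = self.v.forward(flat)
        self._qkv = (q, k, v)
        logits = q @ k.transpose(0, 2, 1) / np.sqrt(c)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        attn = e / e.sum(axis=-1, keepdims=True)
        self._attn = attn
        ctx = attn @ v
        self._ctx = ctx
        out = self.o.forward(ctx)
        return x + out.transpose(0, 2, 1).reshape(b, c, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._xshape
        dflat_out = dy.reshape(b, c, h * w).transpose(0, 2, 1)
        dctx = self.o.backward(dflat_out)
        attn = self._attn
        q, k, v = self._qkv
        dattn = dctx @ v.transpose(0, 2, 1)
        dv = attn.transpose(0, 2, 1) @ dctx
        # softmax backward, rows of attn
        tmp = (dattn * attn).sum(axis=-1, keepdims=True)
        dlogits = attn * (dattn - tmp)
        dq = dlogits @ k / np.sqrt(c)
        dk = dlogits.transpose(0, 2, 1) @ q / np.sqrt(c)
        dflat = self.q.backward(dq) + self.k.backward(dk) + self.v.backward(dv)
        return dy + dflat.transpose(0, 2, 1).reshape(b, c, h, w)


class EmbedBias(Layer):
    """FiLM-style conditioning: add a learned per-channel bias from an
    embedding vector."""

    def __init__(self, emb_dim: int, channels: int, rng: np.random.Generator):
        super().__init__()
        self.dense = Dense(emb_dim, channels, rng, zero_init=True)

    def children(self):
        return [self.dense]

    def forward(self, x: np.ndarray, emb: np.ndarray) -> np.ndarray:
        self._ndim = x.ndim
        bias = self.dense.forward(emb)  # (B, C)
        return x + bias.reshape(bias.shape + (1,) * (x.ndim - 2))

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        axes = tuple(range(2, self._ndim))
        demb = self.dense.backward(dy.sum(axis=axes))
        return dy, demb


def sinusoidal_embedding(values: np.ndarray, dim: int,
                         max_freq: float = 1000.0) -> np.ndarray:
    """(B,) scalars in [0, 1] -> (B, dim) sin/cos features."""
    values = np.atleast_1d(np.asarray(values, dtype=float))
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(max_freq), half))
    ang = values[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class Adam:
    """Adam over every parameter of a layer tree; zeroes grads each step."""

    def __init__(self, root: Layer, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = root.all_layers()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mhat = self.m[li][k] / bc1
                vhat = self.v[li][k] / bc2
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                layer.grads[k][...] = 0.0


def zero_grads(root: Layer) -> None:
    for layer in root.all_layers():
        for k in layer.grads:
            layer.grads[k][...] = 0.0


def get_state(root: Layer) -> list[dict[str, np.ndarray]]:
    return [{k: v.copy() for k, v in l.params.items()} for l in root.all_layers()]


def set_state(root: Layer, state: list[dict[str, np.ndarray]]) -> None:
    for layer, st in zip(root.all_layers(), state):
        for k in layer.params:
            layer.params[k][...] = st[k]
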