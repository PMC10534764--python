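"""Minimal numpy neural-network layers for the small detection models.

Everything here is plain numpy (float32 by default) with explicit
forward/backward passes, which keeps training bit-reproducible given a seed. Layers cache what their
backward pass needs; an SGD-with-momentum optimizer with weight decay and a
step learning-rate schedule drives training.

Only the operations the detectors need are provided: 3D/1D convolutions,
non-overlapping max pooling (ceil mode), zero-stuffing temporal upsampling,
ReLU, and fully connected layers.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

#: float32 keeps the compact models fast on one CPU without hurting accuracy
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), shape).astype(DTYPE)


def _triple(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


class Conv3d(Layer):
    """3D convolution over (N, C, T, H, W) volumes."""

    def __init__(self, cin, cout, kernel=3, stride=1, pad=None,
                 rng: Optional[np.random.Generator] = None, name=""):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        if pad is None:
            pad = tuple(k // 2 for k in self.kernel)
        self.pad = _triple(pad)
        rng = rng or np.random.default_rng(0)
        fan_in = cin * int(np.prod(self.kernel))
        self.W = Param(he_init(rng, (cout, cin) + self.kernel, fan_in), name + ".W")
        self.b = Param(np.zeros(cout, dtype=DTYPE), name + ".b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _out_len(self, n, k, s, p):
        return (n + 2 * p - k) // s + 1

    def forward(self, x):
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        N, C, T, H, W = xp.shape
        To = self._out_len(x.shape[2], kt, st, pt)
        Ho = self._out_len(x.shape[3], kh, sh, ph)
        Wo = self._out_len(x.shape[4], kw, sw, pw)
        acc = np.zeros((N, To, Ho, Wo, self.W.value.shape[0]), dtype=xp.dtype)
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    xs = xp[:, :, it:it + st * To:st, ih:ih + sh * Ho:sh,
                            iw:iw + sw * Wo:sw]
                    acc += np.tensordot(xs, self.W.value[:, :, it, ih, iw],
                                        axes=([1], [1]))
        acc += self.b.value
        self._cache = (xp, x.shape, (To, Ho, Wo))
        return np.moveaxis(acc, -1, 1)

    def backward(self, gout):
        xp, xshape, (To, Ho, Wo) = self._cache
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self.pad
        g = np.moveaxis(gout, 1, -1)  # (N, To, Ho, Wo, cout)
        self.b.grad += g.sum(axis=(0, 1, 2, 3))
        gxp = np.zeros_like(xp)
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    sl = (slice(None), slice(None),
                          slice(it, it + st * To, st),
                          slice(ih, ih + sh * Ho, sh),
                          slice(iw, iw + sw * Wo, sw))
                    xs = xp[sl]
                    # (cout, cin) contribution
                    self.W.grad[:, :, it, ih, iw] += np.tensordot(
                        g, xs, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
                    gxs = np.tensordot(g, self.W.value[:, :, it, ih, iw],
                                       axes=([4], [0]))  # (N,To,Ho,Wo,cin)
                    gxp[sl] += np.moveaxis(gxs, -1, 1)
        N, C, T, H, W = xshape
        return gxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W]


class MaxPool3d(Layer):
    """Non-overlapping max pooling with ceil mode (-inf padding)."""

    def __init__(self, kernel):
        self.kernel = _triple(kernel)
        self._cache = None

    def forward(self, x):
        kt, kh, kw = self.kernel
        N, C, T, H, W = x.shape
        To, Ho, Wo = -(-T // kt), -(-H // kh), -(-W // kw)
        xp = np.full((N, C, To * kt, Ho * kh, Wo * kw), -np.inf, dtype=x.dtype)
        xp[:, :, :T, :H, :W] = x
        r = xp.reshape(N, C, To, kt, Ho, kh, Wo, kw)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            N, C, To, Ho, Wo, kt * kh * kw)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, (To, Ho, Wo))
        return out

    def backward(self, gout):
        idx, xshape, (To, Ho, Wo) = self._cache
        kt, kh, kw = self.kernel
        N, C, T, H, W = xshape
        gr = np.zeros((N, C, To, Ho, Wo, kt * kh * kw), dtype=gout.dtype)
        np.put_along_axis(gr, idx[..., None], gout[..., None], axis=-1)
        gr = gr.reshape(N, C, To, Ho, Wo, kt, kh, kw)
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(
            N, C, To * kt, Ho * kh, Wo * kw)
        return gr[:, :, :T, :H, :W]


class SpatialGlobalMax(Layer):
    """(N, C, T, H, W) -> (N, C, T): max over the spatial extent."""

    def forward(self, x):
        N, C, T, H, W = x.shape
        flat = x.reshape(N, C, T, H * W)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, gout):
        idx, xshape = self._cache
        N, C, T, H, W = xshape
        g = np.zeros((N, C, T, H * W), dtype=gout.dtype)
        np.put_along_axis(g, idx[..., None], gout[..., None], axis=-1)
        return g.reshape(xshape)


class Conv1d(Layer):
    """1D convolution over (N, C, T)."""

    def __init__(self, cin, cout, kernel=3, stride=1, pad=None,
                 rng: Optional[np.random.Generator] = None, name=""):
        self.kernel = int(kernel)
        self.stride = int(stride)
        self.pad = self.kernel // 2 if pad is None else int(pad)
        rng = rng or np.random.default_rng(0)
        self.W = Param(he_init(rng, (cout, cin, self.kernel), cin * self.kernel),
                       name + ".W")
        self.b = Param(np.zeros(cout, dtype=DTYPE), name + ".b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        To = (x.shape[2] + 2 * p - k) // s + 1
        acc = np.zeros((x.shape[0], To, self.W.value.shape[0]), dtype=xp.dtype)
        for ik in range(k):
            xs = xp[:, :, ik:ik + s * To:s]
            acc += np.tensordot(xs, self.W.value[:, :, ik], axes=([1], [1]))
        acc += self.b.value
        self._cache = (xp, x.shape, To)
        return np.moveaxis(acc, -1, 1)

    def backward(self, gout):
        xp, xshape, To = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        g = np.moveaxis(gout, 1, -1)  # (N, To, cout)
        self.b.grad += g.sum(axis=(0, 1))
        gxp = np.zeros_like(xp)
        for ik in range(k):
            sl = (slice(None), slice(None), slice(ik, ik + s * To, s))
            xs = xp[sl]
            self.W.grad[:, :, ik] += np.tensordot(g, xs, axes=([0, 1], [0, 2]))
            gxs = np.tensordot(g, self.W.value[:, :, ik], axes=([2], [0]))
            gxp[sl] += np.moveaxis(gxs, -1, 1)
        return gxp[:, :, p:p + xshape[2]]


class ZeroUpsample1d(Layer):
    """Temporal x2 upsampling by zero stuffing: (N, C, T) -> (N, C, 2T).

    Followed by a Conv1d this realizes a stride-2 transposed convolution.
    """

    def forward(self, x):
        N, C, T = x.shape
        y = np.zeros((N, C, 2 * T), dtype=x.dtype)
        y[:, :, 0::2] = x
        return y

    def backward(self, gout):
        return gout[:, :, 0::2].copy()


class Permute(Layer):
    """Fixed axis permutation, e.g. swapping joint and coordinate axes."""

    def __init__(self, axes):
        self.axes = tuple(axes)
        self._inv = tuple(np.argsort(self.axes))

    def forward(self, x):
        return np.transpose(x, self.axes)

    def backward(self, gout):
        return np.transpose(gout, self._inv)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Linear(Layer):
    def __init__(self, fin, fout, rng: Optional[np.random.Generator] = None, name=""):
        rng = rng or np.random.default_rng(0)
        self.W = Param(he_init(rng, (fin, fout), fin), name + ".W")
        self.b = Param(np.zeros(fout, dtype=DTYPE), name + ".b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gout):
        self._x_flat = self._x
        self.W.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_ce(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the leading axis; returns (loss, dlogits)."""
    probs = softmax(logits, axis=-1)
    n = logits.shape[0]
    idx = (np.arange(n), np.asarray(targets, dtype=int))
    loss = float(-np.log(np.clip(probs[idx], 1e-12, None)).mean())
    grad = probs.copy()
    grad[idx] -= 1.0
    return loss, grad / n


class SGD:
    """SGD with momentum, decoupled-style weight decay, and step lr decay."""

    def __init__(self, params: Sequence[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, lr_decay: float = 1.0,
                 lr_decay_every: Optional[int] = None,
                 clip_norm: Optional[float] = None):
        self.params = list(params)
        self.base_lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_decay = lr_decay
        self.lr_decay_every = lr_decay_every
        self.clip_norm = clip_norm
        self.iteration = 0
        self._vel = [np.zeros_like(p.value) for p in self.params]

    @property
    def lr(self) -> float:
        if not self.lr_decay_every:
            return self.base_lr
        k = self.iteration // self.lr_decay_every
        return self.base_lr * (self.lr_decay ** k)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        lr = self.lr
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    p.grad *= scale
        for p, v in zip(self.params, self._vel):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v -= lr * g
            p.value += v
        self.iteration += 1

    def max_update_magnitude(self) -> float:
        return max(float(np.abs(v).max()) for v in self._vel) if self._vel else 0.0
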