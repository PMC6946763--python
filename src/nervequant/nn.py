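"""Minimal numpy CNN machinery for the U-Net segmenter.

Layers operate on (N, C, H, W) float32 tensors and implement explicit
forward/backward passes; convolutions go through im2col so the heavy
lifting is a single BLAS matmul.  Gradient correctness is verified against
numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "Dropout", "MaxPool2", "Upsample2", "Sigmoid",
           "UNet", "Adam"]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) columns for a same-padded 3x3 kernel."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


class Conv2d:
    """3x3 (or 1x1) same-padding convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        o = self.W.shape[0]
        if self.kernel == 1:
            y = np.tensordot(x, self.W[:, :, 0, 0], axes=([1], [1]))
            y = y.transpose(0, 3, 1, 2) + self.b[None, :, None, None]
            self._cache = (x, None)
            return np.ascontiguousarray(y)
        cols = _im2col3(x)
        y = cols @ self.W.reshape(o, -1).T + self.b
        self._cache = (x.shape, cols)
        return y.reshape(n, h, w, o).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        o = self.W.shape[0]
        if self.kernel == 1:
            x, _ = self._cache
            self.gW[:] = np.tensordot(dy, x, axes=([0, 2, 3], [0, 2, 3]))[..., None, None]
            self.gb[:] = dy.sum(axis=(0, 2, 3))
            dx = np.tensordot(dy, self.W[:, :, 0, 0], axes=([1], [0]))
            return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        (n, c, h, w), cols = self._cache
        dy2 = dy.transpose(0, 2, 3, 1).reshape(-1, o)
        self.gW[:] = (dy2.T @ cols).reshape(self.W.shape)
        self.gb[:] = dy2.sum(axis=0)
        # dx = full correlation of dy with the flipped, transposed kernel
        wt = np.ascontiguousarray(self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dcols = _im2col3(dy)
        dx = dcols @ wt.reshape(c, -1).T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class ReLU:
    params: list = []

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid:
    params: list = []

    def forward(self, x, training=False):
        # clip pre-activations: float32 exp overflows past ~88
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -80.0, 80.0)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout:
    """Inverted dropout; identity at inference."""

    params: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool2:
    params: list = []

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._idx[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Upsample2:
    """2x nearest-neighbour upsampling."""

    params: list = []

    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """conv-relu conv-relu (+ optional dropout) unit."""

    def __init__(self, in_ch, out_ch, rng, dropout_rate=0.0, drop_rng=None):
        self.layers = [Conv2d(in_ch, out_ch, 3, rng), ReLU(),
                       Conv2d(out_ch, out_ch, 3, rng), ReLU()]
        if dropout_rate > 0:
            self.layers.append(Dropout(dropout_rate, drop_rng))

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """U-shaped encoder/decoder with skip concatenation and a sigmoid head.

    Channels double per encoder level from ``base_channels``; dropout sits
    after each encoder block and the bottleneck; upsampling is 2x nearest
    neighbour followed by a 3x3 conv.
    """

    def __init__(self, depth: int = 4, base_channels: int = 32,
                 dropout_rate: float = 0.2, seed: int = 0):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        ss = np.random.SeedSequence(seed).spawn(2)
        rng = np.random.default_rng(ss[0])
        drop_rng = np.random.default_rng(ss[1])
        self.depth = depth
        self.base_channels = base_channels
        ch = [base_channels * 2 ** i for i in range(depth + 1)]
        self.enc = [_Block(1 if i == 0 else ch[i - 1], ch[i], rng,
                           dropout_rate, drop_rng) for i in range(depth)]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(ch[depth - 1], ch[depth], rng,
                                 dropout_rate, drop_rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.upconvs = [Conv2d(ch[i + 1], ch[i], 3, rng) for i in range(depth)]
        self.dec = [_Block(2 * ch[i], ch[i], rng) for i in range(depth)]
        self.head = Conv2d(ch[0], 1, 1, rng)
        self.out_act = Sigmoid()

    @property
    def params(self):
        mods = (self.enc + [self.bottleneck] + self.upconvs + self.dec
                + [self.head])
        return [p for m in mods for p in m.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        side = x.shape[2]
        if x.shape[2] != x.shape[3]:
            raise ValueError(f"input must be square, got {x.shape[2:]}")
        if side % (2 ** self.depth) != 0:
            raise ValueError(
                f"input side {side} not divisible by 2^depth = {2 ** self.depth}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_ch = []
        for i in reversed(range(self.depth)):
            x = self.ups[i].forward(x, training)
            x = self.upconvs[i].forward(x, training)
            self._skip_ch.append(x.shape[1])
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i].forward(x, training)
        x = self.head.forward(x, training)
        y = self.out_act.forward(x, training)
        self._skips = skips
        return y[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); accumulates parameter grads."""
        dy = np.asarray(dy, dtype=np.float32)
        if dy.ndim == 2:
            dy = dy[None]
        g = self.out_act.backward(dy[:, None])
        g = self.head.backward(g)
        dskips = [None] * self.depth
        for k, i in enumerate(range(self.depth)):
            g = self.dec[i].backward(g)
            nskip = self._skips[i].shape[1]
            dskips[i] = g[:, :nskip]
            g = g[:, nskip:]
            g = self.upconvs[i].backward(g)
            g = self.ups[i].backward(g)
        g = self.bottleneck.backward(g)
        for i in reversed(range(self.depth)):
            g = self.pools[i].backward(g)
            g = g + dskips[i]
            g = self.enc[i].backward(g)

    def weight_checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p, _ in self.params))


class Adam:
    """Adam optimiser over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
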