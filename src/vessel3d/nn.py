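"""A small numpy CNN toolkit: stride-1 'same' convolutions with manual
backpropagation, 2x max-pooling / nearest upsampling, a compact U-net
(encoder-decoder with skip connections), softmax cross-entropy, AdamW and a
one-cycle learning-rate schedule.

Arrays are NCHW float64. The U-net here is deliberately compact — a few
levels and narrow channels — which is adequate for the two-class vessel
segmentation and flow-prediction problems in this package.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "UpNearest2",
    "UNet",
    "softmax_cross_entropy",
    "AdamW",
    "OneCycleLR",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) with zero 'same' padding (odd k)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    v = v.transpose(0, 2, 3, 1, 4, 5)  # (N, H, W, C, k, k)
    n, h, w = v.shape[:3]
    return np.ascontiguousarray(v).reshape(n * h * w, -1)


class Conv2d:
    """Stride-1 'same' 2D convolution (odd kernel)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        rng = rng or np.random.default_rng()
        if zero_init:
            # near-zero head: the flow starts at (almost) the identity warp but
            # still passes gradient to the encoder from the first step
            w = rng.normal(0.0, 1e-3, (out_ch, in_ch, k, k))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (in_ch * k * k)), (out_ch, in_ch, k, k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        self._cols, self._shape = cols, x.shape
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.bias.value
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        g = gy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.weight.grad += (g.T @ self._cols).reshape(self.weight.value.shape)
        self.bias.grad += g.sum(axis=0)
        # dx = 'same' convolution of gy with the transposed, 180-rotated kernels
        w_t = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, k, k)
        cols_g = _im2col(gy, self.k)
        dx = cols_g @ w_t.reshape(self.in_ch, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2:
    """2x2 max pooling; input H and W must be even."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._arg = v.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(v, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        v = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(v, self._arg[..., None], gy[..., None], axis=-1)
        return v.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpNearest2:
    """2x nearest-neighbour upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.layers = [Conv2d(in_ch, out_ch, rng=rng), ReLU(), Conv2d(out_ch, out_ch, rng=rng), ReLU()]

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class UNet:
    """Encoder-decoder with skip connections and a 1x1 output head.

    ``depth`` pooling levels; channels double per level from ``base``. Input
    H and W must be divisible by ``2**depth``. ``final_zero=True``
    zero-initializes the head so the network starts as the zero map (used for
    flow prediction, which should begin at the identity warp).
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        base: int = 8,
        depth: int = 2,
        seed: int = 0,
        final_zero: bool = False,
    ):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc = []
        ch = in_ch
        for d in range(depth):
            self.enc.append(_Block(ch, base * 2**d, rng))
            ch = base * 2**d
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(ch, base * 2**depth, rng)
        self.ups = [UpNearest2() for _ in range(depth)]
        self.dec = []
        ch = base * 2**depth
        for d in range(depth - 1, -1, -1):
            skip = base * 2**d
            self.dec.append(_Block(ch + skip, skip, rng))
            ch = skip
        self.head = Conv2d(ch, out_ch, k=1, rng=rng, zero_init=final_zero)

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.enc:
            ps += b.params()
        ps += self.bottleneck.params()
        for b in self.dec:
            ps += b.params()
        ps += self.head.params()
        return ps

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % 2**self.depth or x.shape[3] % 2**self.depth:
            raise ValueError(f"input H, W must be divisible by {2**self.depth}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(skip.shape[1])
            x = blk.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, gy: np.ndarray) -> None:
        g = self.head.backward(gy)
        g_skips = []
        for blk, up, sc in zip(reversed(self.dec), reversed(self.ups), reversed(self._skip_ch)):
            g = blk.backward(g)
            g_skips.append(g[:, :sc])
            g = up.backward(g[:, sc:])
        g = self.bottleneck.backward(g)
        g_skips.reverse()  # g_skips[d] belongs to encoder level depth-1-d after reverse
        for d in range(self.depth - 1, -1, -1):
            g = self.pools[d].backward(g)
            g = g + g_skips[self.depth - 1 - d]
            g = self.enc[d].backward(g)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over all pixels; returns (loss, dloss/dlogits).

    ``logits``: (N, K, H, W); ``labels``: (N, H, W) integer class indices.
    """
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n, _, h, w = logits.shape
    picked = log_probs.transpose(0, 2, 3, 1)[
        np.arange(n)[:, None, None], np.arange(h)[None, :, None], np.arange(w)[None, None, :], labels
    ]
    loss = -picked.mean()
    probs = np.exp(log_probs)
    onehot = np.zeros_like(probs)
    onehot_t = onehot.transpose(0, 2, 3, 1)
    onehot_t[
        np.arange(n)[:, None, None], np.arange(h)[None, :, None], np.arange(w)[None, None, :], labels
    ] = 1.0
    dlogits = (probs - onehot) / (n * h * w)
    return float(loss), dlogits


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.value)


class OneCycleLR:
    """One-cycle schedule: cosine ramp from lr/div up to max_lr over
    ``pct_start`` of the steps, then cosine anneal to max_lr/final_div."""

    def __init__(
        self,
        max_lr: float,
        total_steps: int,
        pct_start: float = 0.3,
        div_factor: float = 25.0,
        final_div_factor: float = 1e3,
    ):
        self.max_lr = max_lr
        self.total = max(1, total_steps)
        self.pct = pct_start
        self.lr0 = max_lr / div_factor
        self.lr_end = max_lr / final_div_factor

    def lr(self, step: int) -> float:
        up = self.pct * self.total
        if step < up:
            f = step / max(1.0, up)
            return self.lr0 + (self.max_lr - self.lr0) * 0.5 * (1 - np.cos(np.pi * f))
        f = (step - up) / max(1.0, self.total - up)
        return self.lr_end + (self.max_lr - self.lr_end) * 0.5 * (1 + np.cos(np.pi * min(f, 1.0)))
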