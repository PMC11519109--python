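"""Minimal 2D convolutional network machinery (numpy, hand-written backprop).

Implements exactly what the desk-scale reconstruction and detection models
need: same-padded 2D convolutions, ReLU, 2x2 average pooling with nearest
upsampling, channel concatenation, and Adam.  Arrays are ``(B, C, H, W)``.
Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "Adam", "UNet2D"]


class Conv2D:
    """Same-padded k x k convolution with bias."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        zero_init: bool = False,
    ) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        if zero_init:
            self.weight = np.zeros((out_ch, in_ch, kernel, kernel))
        else:  # He initialisation
            std = np.sqrt(2.0 / (in_ch * kernel * kernel))
            self.weight = rng.normal(scale=std, size=(out_ch, in_ch, kernel, kernel))
        self.bias = np.zeros(out_ch)
        self._win: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    def _windows(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        return sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = self._windows(x)
        return (
            np.einsum("bchwij,ocij->bohw", self._win, self.weight, optimize=True)
            + self.bias[None, :, None, None]
        )

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        assert self._win is not None, "forward must run before backward"
        dw = np.einsum("bchwij,bohw->ocij", self._win, dy, optimize=True)
        db = dy.sum(axis=(0, 2, 3))
        # dx: full correlation of dy with the spatially flipped kernels
        p = self.kernel // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        dyw = sliding_window_view(dyp, (self.kernel, self.kernel), axis=(2, 3))
        w_flip = self.weight[:, :, ::-1, ::-1]
        dx = np.einsum("bohwij,ocij->bchw", dyw, w_flip, optimize=True)
        self._win = None
        return dx, [dw, db]


def avgpool2(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("avgpool2 needs even spatial extents")
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


def upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    b, c, h, w = dy.shape
    return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


@dataclass
class Adam:
    """Adam optimiser over a flat list of parameter arrays."""

    lr: float = 4e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1 - self.beta1**self._t
        b2t = 1 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class UNet2D:
    """Two-level encoder-decoder with a skip connection, slice-wise.

    input -> conv_a(k) + ReLU -> [skip]
           -> avgpool2 -> conv_b(3) + ReLU -> upsample2
           -> concat(skip, up) -> conv_c(3) -> head

    ``head`` is "linear" (reconstruction residual; conv_c is zero-initialised
    so the untrained residual model is the identity) or "sigmoid"
    (detection likelihood).
    """

    def __init__(
        self,
        channels: int = 8,
        head: str = "linear",
        kernel: int = 3,
        seed: int = 0,
    ) -> None:
        if head not in ("linear", "sigmoid"):
            raise ValueError("head must be 'linear' or 'sigmoid'")
        rng = np.random.default_rng(seed)
        self.head = head
        self.channels = channels
        self.conv_a = Conv2D(1, channels, kernel, rng)
        self.conv_b = Conv2D(channels, channels, 3, rng)
        self.conv_c = Conv2D(2 * channels, 1, 3, rng, zero_init=(head == "linear"))
        self._cache: dict[str, np.ndarray] = {}

    @property
    def params(self) -> list[np.ndarray]:
        return self.conv_a.params + self.conv_b.params + self.conv_c.params

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, H, W) with even H, W; returns (B, H, W)."""
        xb = x[:, None, :, :]
        a = self.conv_a.forward(xb)
        a_relu = np.maximum(a, 0.0)
        d = avgpool2(a_relu)
        b = self.conv_b.forward(d)
        b_relu = np.maximum(b, 0.0)
        u = upsample2(b_relu)
        cat = np.concatenate([a_relu, u], axis=1)
        z = self.conv_c.forward(cat)[:, 0]
        self._cache = {"a": a, "b": b, "z": z}
        if self.head == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-z))
            self._cache["out"] = out
            return out
        return z

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients of the cached forward pass; dout is d(loss)/d(output)."""
        c = self._cache
        if self.head == "sigmoid":
            dz = dout * c["out"] * (1.0 - c["out"])
        else:
            dz = dout
        dcat, g_c = self.conv_c.backward(dz[:, None])
        n = self.channels
        da_relu = dcat[:, :n]
        du = dcat[:, n:]
        db_relu = upsample2_backward(du)
        db = db_relu * (c["b"] > 0)
        dd, g_b = self.conv_b.backward(db)
        da_relu = da_relu + avgpool2_backward(dd)
        da = da_relu * (c["a"] > 0)
        _, g_a = self.conv_a.backward(da)
        return g_a + g_b + g_c
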