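"""Minimal NumPy encoder-decoder network with hand-written backprop.

A U-Net-style fully convolutional net: per resolution level two 3x3
convolutions with ReLU, 2x2 max pooling on the contracting path, nearest
up-sampling plus skip concatenation on the expanding path, and a final 1x1
convolution with a sigmoid head.  Data layout is NHWC, float32.

Convolutions use an im2col view (numpy sliding_window_view) feeding a
single GEMM; backward recomputes the column matrix from the cached padded
input, which keeps the activation memory linear in the layer inputs.  The
input gradient of a same-padded 3x3 correlation is the correlation of the
output gradient with the spatially flipped, channel-transposed kernels.

Everything is deterministic: seeded He initialization, no dropout, pure
NumPy arithmetic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "Adam", "dice_loss_and_grad", "dice_bce_loss_and_grad"]


def _conv3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 correlation as nine shifted GEMMs.

    x: (N,H,W,C), w: (3,3,C,F), b: (F,).  Accumulating per-tap GEMMs beats
    a single im2col GEMM here: it avoids materializing the 9x column
    matrix, which is memory-bandwidth bound at these sizes.
    """
    N, H, W, C = x.shape
    F = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((N, H, W, F), dtype=np.float32)
    out[:] = b
    acc = out.reshape(-1, F)
    for dy in range(3):
        for dx in range(3):
            xs = np.ascontiguousarray(xp[:, dy : dy + H, dx : dx + W, :])
            acc += xs.reshape(-1, C) @ w[dy, dx]
    return out


def _conv3_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padded 3x3 correlation.

    Returns (dx, dw, db)."""
    N, H, W, C = x.shape
    F = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dym = np.ascontiguousarray(dy.reshape(N * H * W, F))
    dw = np.empty_like(w)
    for ky in range(3):
        for kx in range(3):
            xs = np.ascontiguousarray(xp[:, ky : ky + H, kx : kx + W, :])
            dw[ky, kx] = xs.reshape(-1, C).T @ dym
    db = dym.sum(axis=0)
    # dx = correlation of dy with flipped kernels, swapping in/out channels.
    w_flip = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,F,C)
    dx = _conv3(dy, np.ascontiguousarray(w_flip), np.zeros(C, dtype=w.dtype))
    return dx, dw, db


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns (pooled, argmax indices for backward)."""
    N, H, W, C = x.shape
    xr = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    xr = xr.reshape(N, H // 2, W // 2, 4, C)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def _maxpool2_backward(dy: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    N, H, W, C = in_shape
    dxr = np.zeros((N, H // 2, W // 2, 4, C), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
    dxr = dxr.reshape(N, H // 2, W // 2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    return dxr.reshape(N, H, W, C)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    N, H, W, C = dy.shape
    return dy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class UNet:
    """Encoder-decoder segmenter.

    depth : number of 2x downsampling stages; input H, W must be divisible
        by 2**depth (callers enforce the stricter divisible-by-32 contract).
    base_channels : channel width of the first level; doubles per level.
    """

    def __init__(self, depth: int = 3, base_channels: int = 8, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        self.base_channels = base_channels
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)

        def he(name, kh, kw, cin, cout):
            std = np.sqrt(2.0 / (kh * kw * cin))
            self.params[f"{name}_w"] = rng.normal(
                0.0, std, size=(kh, kw, cin, cout)
            ).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        cin = 1
        for d in range(depth):
            c = base_channels * 2**d
            he(f"enc{d}a", 3, 3, cin, c)
            he(f"enc{d}b", 3, 3, c, c)
            cin = c
        cb = base_channels * 2**depth
        he("botta", 3, 3, cin, cb)
        he("bottb", 3, 3, cb, cb)
        cup = cb
        for d in reversed(range(depth)):
            c = base_channels * 2**d
            he(f"dec{d}a", 3, 3, cup + c, c)
            he(f"dec{d}b", 3, 3, c, c)
            cup = c
        he("out", 1, 1, cup, 1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "UNet":
        m = UNet.__new__(UNet)
        m.depth, m.base_channels, m.seed = self.depth, self.base_channels, self.seed
        m.params = {k: v.copy() for k, v in self.params.items()}
        return m

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (N,H,W) or (N,H,W,1) float32 in [-1,1] -> sigmoid map (N,H,W)."""
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(np.float32, copy=False)
        p = self.params
        cache = {"x0": x} if want_cache else None
        h = x
        skips = []
        for d in range(self.depth):
            a = _conv3(h, p[f"enc{d}a_w"], p[f"enc{d}a_b"])
            ra = np.maximum(a, 0.0)
            b = _conv3(ra, p[f"enc{d}b_w"], p[f"enc{d}b_b"])
            rb = np.maximum(b, 0.0)
            pooled, idx = _maxpool2(rb)
            if want_cache:
                cache[f"enc{d}"] = (h, a, ra, b, rb, idx)
            skips.append(rb)
            h = pooled
        a = _conv3(h, p["botta_w"], p["botta_b"])
        ra = np.maximum(a, 0.0)
        b = _conv3(ra, p["bottb_w"], p["bottb_b"])
        rb = np.maximum(b, 0.0)
        if want_cache:
            cache["bott"] = (h, a, ra, b)
        h = rb
        for d in reversed(range(self.depth)):
            up = _upsample2(h)
            cat = np.concatenate([up, skips[d]], axis=-1)
            a = _conv3(cat, p[f"dec{d}a_w"], p[f"dec{d}a_b"])
            ra = np.maximum(a, 0.0)
            b = _conv3(ra, p[f"dec{d}b_w"], p[f"dec{d}b_b"])
            rb = np.maximum(b, 0.0)
            if want_cache:
                cache[f"dec{d}"] = (cat, a, ra, b)
            h = rb
        z = _conv3_1x1(h, p["out_w"], p["out_b"])
        y = _sigmoid(z)
        if want_cache:
            cache["head"] = (h, z, y)
            return y[..., 0], cache
        return y[..., 0]

    def backward(self, cache, dprob: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss wrt all parameters.

        ``dprob``: dL/d(sigmoid output), shape (N,H,W).
        """
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h_in, z, y = cache["head"]
        dz = (dprob[..., None] * y * (1.0 - y)).astype(np.float32)
        dh, grads["out_w"], grads["out_b"] = _conv1x1_backward(
            h_in, p["out_w"], dz
        )
        for d in range(self.depth):
            cat, a, ra, b = cache[f"dec{d}"]
            db_ = dh * (b > 0)
            dra, grads[f"dec{d}b_w"], grads[f"dec{d}b_b"] = _conv3_backward(
                ra, p[f"dec{d}b_w"], db_
            )
            da = dra * (a > 0)
            dcat, grads[f"dec{d}a_w"], grads[f"dec{d}a_b"] = _conv3_backward(
                cat, p[f"dec{d}a_w"], da
            )
            cup = cat.shape[-1] - (self.base_channels * 2**d)
            dup = dcat[..., :cup]
            dskip = dcat[..., cup:]
            dh = _upsample2_backward(dup)
            cache[f"skipgrad{d}"] = dskip
        h_in, a, ra, b = cache["bott"]
        db_ = dh * (b > 0)
        dra, grads["bottb_w"], grads["bottb_b"] = _conv3_backward(
            ra, p["bottb_w"], db_
        )
        da = dra * (a > 0)
        dh, grads["botta_w"], grads["botta_b"] = _conv3_backward(
            h_in, p["botta_w"], da
        )
        for d in reversed(range(self.depth)):
            h_in, a, ra, b, rb, idx = cache[f"enc{d}"]
            drb = _maxpool2_backward(dh, idx, rb.shape) + cache[f"skipgrad{d}"]
            db_ = drb * (b > 0)
            dra, grads[f"enc{d}b_w"], grads[f"enc{d}b_b"] = _conv3_backward(
                ra, p[f"enc{d}b_w"], db_
            )
            da = dra * (a > 0)
            dh, grads[f"enc{d}a_w"], grads[f"enc{d}a_b"] = _conv3_backward(
                h_in, p[f"enc{d}a_w"], da
            )
        return grads


def _conv3_1x1(x, w, b):
    if w.shape[0] == 1 and w.shape[1] == 1:
        N, H, W, C = x.shape
        out = x.reshape(-1, C) @ w.reshape(C, -1) + b
        return out.reshape(N, H, W, -1)
    return _conv3(x, w, b)


def _conv1x1_backward(x, w, dy):
    N, H, W, C = x.shape
    F = w.shape[-1]
    xm = x.reshape(-1, C)
    dym = dy.reshape(-1, F)
    dw = (xm.T @ dym).reshape(1, 1, C, F)
    db = dym.sum(axis=0)
    dx = (dym @ w.reshape(C, F).T).reshape(N, H, W, C)
    return dx, dw, db


def dice_loss_and_grad(
    prob: np.ndarray, target: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """Soft Dice loss over a batch and its gradient wrt ``prob``.

    L = 1 - (2 Σ p·g + s) / (Σ p + Σ g + s), sums over the whole batch.
    The smoothing constant keeps empty-mask frames (closed glottis)
    well-defined and gently rewards empty predictions on empty targets.
    """
    p = prob.astype(np.float64, copy=False)
    g = target.astype(np.float64, copy=False)
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + smooth
    dice = (2.0 * inter + smooth) / denom
    # d dice / dp = (2 g · denom - (2 inter + smooth)) / denom^2
    grad = -(2.0 * g * denom - (2.0 * inter + smooth)) / (denom**2)
    return 1.0 - dice, grad.astype(np.float32)


def dice_bce_loss_and_grad(
    prob: np.ndarray,
    target: np.ndarray,
    bce_weight: float = 0.5,
    smooth: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Soft Dice plus weighted binary cross-entropy, with gradient wrt prob.

    Batch-pooled Dice alone has a degenerate basin on small batches with
    many empty (closed-glottis) targets: predicting nothing everywhere
    scores a near-perfect smoothed Dice.  The pixel-wise BCE term anchors
    open-frame glottis pixels and removes that collapse mode.
    """
    dloss, dgrad = dice_loss_and_grad(prob, target, smooth=smooth)
    p = np.clip(prob.astype(np.float64, copy=False), 1e-7, 1.0 - 1e-7)
    g = target.astype(np.float64, copy=False)
    bce = float(-np.mean(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)))
    bgrad = ((p - g) / (p * (1.0 - p))) / p.size
    loss = dloss + bce_weight * bce
    grad = dgrad + (bce_weight * bgrad).astype(np.float32)
    return loss, grad


class Adam:
    """Adam optimizer over a parameter dict, with global grad-norm clipping.

    Occasional gradient spikes — e.g. a batch of all-empty targets meeting
    a few confident positive predictions — can overshoot a ReLU network
    into a dead, unrecoverable state; clipping the global gradient norm
    caps such steps while leaving ordinary updates untouched.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 10.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        if self.lr == 0.0:
            return
        if self.clip_norm is not None:
            gnorm = np.sqrt(
                sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values())
            )
            if gnorm > self.clip_norm:
                scale = np.float32(self.clip_norm / gnorm)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32, copy=False)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )
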