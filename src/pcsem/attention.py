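"""Channel and spatial attention blocks: SE, CBAM, and P-CSEM.

All three operate on a feature map ``x`` of shape (N, C, H, W) — or (C, H, W)
for a single sample — and return a gated map of identical shape.

* **SE** (squeeze-and-excitation): a channel gate.  Global average pooling
  squeezes each channel to a scalar, a two-layer bottleneck MLP (hidden width
  ``C // R``) excites it back, and a sigmoid bounds the gate in (0, 1) before
  the elementwise rescaling of the input.
* **CBAM**: a channel stage like SE but fed by both global average and global
  max pooling through a *shared* MLP, followed by a spatial stage — the
  channel-refined map is pooled across channels (average and max), the two
  planes are concatenated and passed through a single 7×7 convolution and a
  sigmoid to give an H×W gate.
* **P-CSEM** (parallel-convolutional squeezed and excitation module): two
  branches run in parallel on the *same* input.  Branch one is the SE channel
  gate.  Branch two averages the channels to a single H×W plane, excites it to
  8 channels with a 3×3 convolution (7 tool classes plus one background
  channel), applies ReLU, squeezes back to one channel with a second 3×3
  convolution, and bounds it with a sigmoid.  The two gates are multiplied
  (broadcast C × H×W) and rescale the input.

Both P-CSEM branch outputs pass through sigmoids so the combined gate lies in
(0, 1) and the block is a pure attenuation, like SE; the channel branch
inherits this from the SE design and the spatial branch is squashed before
the product so "rescaling" keeps its multiplicative-gate meaning.

Blocks expose ``gate_override``: setting it to 1.0 clamps every gate to one,
turning the block into the identity — used for ablation equivalence checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Linear, Module, Parameter, kaiming_uniform

KINDS = ("se", "cbam", "pcsem")


@dataclass
class AttentionConfig:
    """Hyper-parameters of one attention block.

    Parameters
    ----------
    kind : {"se", "cbam", "pcsem"}
    channels : int
        Channel width C of the feature map the block is attached to.
    reduction : int, default 16
        Bottleneck divisor R of the channel MLP (hidden width ``C // R``,
        floored, minimum 1).  4, 8 and 16 are the studied values; any
        positive integer is accepted.
    spatial_kernel : int or None
        Odd kernel size of the spatial convolution(s); defaults to 7 for
        CBAM and 3 for P-CSEM.
    pcsem_mid_channels : int, default 8
        Width of the excited spatial space in P-CSEM (7 tools + 1).
    """

    kind: str
    channels: int
    reduction: int = 16
    spatial_kernel: int | None = None
    pcsem_mid_channels: int = 8

    def __post_init__(self):
        kind = self.kind.lower()
        if kind not in KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}; expected one of {KINDS}")
        self.kind = kind
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.reduction < 1:
            raise ValueError("reduction must be a positive integer")
        if self.spatial_kernel is None:
            self.spatial_kernel = 7 if kind == "cbam" else 3
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")

    @property
    def bottleneck(self) -> int:
        return max(self.channels // self.reduction, 1)


def _validate(x: np.ndarray, channels: int) -> tuple[np.ndarray, bool]:
    """Coerce to (N,C,H,W) float; reject wrong widths and non-finite data.

    float64 input stays float64 (numpy upcasts through the float32 weights),
    which lets exact scalar oracles run at full precision.
    """
    x = np.asarray(x)
    if x.dtype not in (np.float32, np.float64):
        x = x.astype(np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.ndim != 4:
        raise ValueError(f"expected a (C,H,W) or (N,C,H,W) array, got shape {x.shape}")
    if x.shape[1] != channels:
        raise ValueError(
            f"feature map has {x.shape[1]} channels but the block was built for {channels}")
    if not np.isfinite(x).all():
        raise ValueError("feature map contains non-finite entries")
    return x, squeeze


class SEBlock(Module):
    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.reduction = reduction
        mid = max(channels // reduction, 1)
        self.fc1 = Linear(channels, mid, rng)
        self.fc2 = Linear(mid, channels, rng)
        self.gate_override: float | None = None

    def channel_gate(self, x: np.ndarray) -> np.ndarray:
        s = x.mean(axis=(2, 3))
        pre = self.fc1.forward(s)
        h = np.maximum(pre, 0.0)
        self._relu_mask = pre > 0
        a = self.fc2.forward(h)
        return 1.0 / (1.0 + np.exp(-a))

    def forward(self, x, train=False):
        x, squeeze = _validate(x, self.channels)
        if self.gate_override is not None:
            self._cache = None
            y = x * self.gate_override
            return y[0] if squeeze else y
        g = self.channel_gate(x)
        self._cache = (x, g)
        y = x * g[:, :, None, None]
        return y[0] if squeeze else y

    def backward(self, dout):
        if self._cache is None:
            return dout * (self.gate_override or 1.0)
        x, g = self._cache
        h, w = x.shape[2], x.shape[3]
        dx = dout * g[:, :, None, None]
        dg = (dout * x).sum(axis=(2, 3))
        da = dg * g * (1.0 - g)
        dh = self.fc2.backward(da)
        dpre = np.where(self._relu_mask, dh, 0.0)
        ds = self.fc1.backward(dpre)
        dx += ds[:, :, None, None] / (h * w)
        return dx


class CBAMBlock(Module):
    """Channel stage (GAP ∥ GMP through a shared MLP) then spatial stage."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.reduction = reduction
        mid = max(channels // reduction, 1)
        # shared MLP applied to both pooled vectors; parameters held directly
        # because each Linear caches a single forward
        self.w1 = Parameter(kaiming_uniform(rng, (mid, channels), channels), "w1")
        self.b1 = Parameter(np.zeros(mid), "b1")
        self.w2 = Parameter(kaiming_uniform(rng, (channels, mid), mid), "w2")
        self.b2 = Parameter(np.zeros(channels), "b2")
        self.conv = Conv2d(2, 1, spatial_kernel, rng, padding=spatial_kernel // 2)
        self.gate_override: float | None = None

    def _mlp(self, s):
        pre = s @ self.w1.value.T + self.b1.value
        h = np.maximum(pre, 0.0)
        return pre, h, h @ self.w2.value.T + self.b2.value

    def _mlp_back(self, da, pre, h, s):
        self.w2.grad += da.T @ h
        self.b2.grad += da.sum(axis=0)
        dh = da @ self.w2.value
        dpre = np.where(pre > 0, dh, 0.0)
        self.w1.grad += dpre.T @ s
        self.b1.grad += dpre.sum(axis=0)
        return dpre @ self.w1.value

    def forward(self, x, train=False):
        x, squeeze = _validate(x, self.channels)
        if self.gate_override is not None:
            self._cache = None
            y = x * self.gate_override ** 2  # both stages clamped
            return y[0] if squeeze else y
        n, c, h, w = x.shape
        sa = x.mean(axis=(2, 3))
        sm = x.max(axis=(2, 3))
        arg_hw = x.reshape(n, c, h * w).argmax(axis=2)
        pa_, ha_, aa = self._mlp(sa)
        pm_, hm_, am = self._mlp(sm)
        g = 1.0 / (1.0 + np.exp(-(aa + am)))
        x1 = x * g[:, :, None, None]
        p_avg = x1.mean(axis=1, keepdims=True)
        p_max = x1.max(axis=1, keepdims=True)
        arg_c = x1.argmax(axis=1)
        cat = np.concatenate([p_avg, p_max], axis=1)
        conv_out = self.conv.forward(cat)
        gs = 1.0 / (1.0 + np.exp(-conv_out))
        self._cache = (x, sa, sm, arg_hw, pa_, ha_, pm_, hm_, g, x1, arg_c, gs)
        y = x1 * gs
        return y[0] if squeeze else y

    def backward(self, dout):
        if self._cache is None:
            return dout * (self.gate_override or 1.0) ** 2
        (x, sa, sm, arg_hw, pa_, ha_, pm_, hm_, g, x1, arg_c, gs) = self._cache
        n, c, h, w = x.shape
        dx1 = dout * gs
        dgs = (dout * x1).sum(axis=1, keepdims=True)
        dconv = dgs * gs * (1.0 - gs)
        dcat = self.conv.backward(dconv)
        dx1 += dcat[:, 0:1] / c
        dmax = dcat[:, 1]
        sel = np.zeros_like(dx1)
        np.put_along_axis(sel, arg_c[:, None], dmax[:, None], axis=1)
        dx1 += sel
        # channel stage
        dx = dx1 * g[:, :, None, None]
        dg = (dx1 * x).sum(axis=(2, 3))
        da = dg * g * (1.0 - g)
        dsa = self._mlp_back(da, pa_, ha_, sa)
        dsm = self._mlp_back(da, pm_, hm_, sm)
        dx += dsa[:, :, None, None] / (h * w)
        flat = np.zeros((n, c, h * w), dtype=dx.dtype)
        np.put_along_axis(flat, arg_hw[:, :, None], dsm[:, :, None], axis=2)
        dx += flat.reshape(n, c, h, w)
        return dx


class PCSEMBlock(Module):
    """Parallel channel (SE-style) and convolutional spatial gates."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 3,
                 mid_channels: int = 8, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.reduction = reduction
        mid = max(channels // reduction, 1)
        self.fc1 = Linear(channels, mid, rng)
        self.fc2 = Linear(mid, channels, rng)
        pad = spatial_kernel // 2
        self.conv1 = Conv2d(1, mid_channels, spatial_kernel, rng, padding=pad)
        self.conv2 = Conv2d(mid_channels, 1, spatial_kernel, rng, padding=pad)
        self.gate_override: float | None = None

    def forward(self, x, train=False):
        x, squeeze = _validate(x, self.channels)
        if self.gate_override is not None:
            self._cache = None
            y = x * self.gate_override
            return y[0] if squeeze else y
        # channel branch
        s = x.mean(axis=(2, 3))
        pre = self.fc1.forward(s)
        hch = np.maximum(pre, 0.0)
        a = self.fc2.forward(hch)
        g = 1.0 / (1.0 + np.exp(-a))
        # spatial branch: channel-average plane, conv-excite, conv-squeeze
        m = x.mean(axis=1, keepdims=True)
        u_pre = self.conv1.forward(m)
        u = np.maximum(u_pre, 0.0)
        v = self.conv2.forward(u)
        gs = 1.0 / (1.0 + np.exp(-v))
        self._cache = (x, pre, g, u_pre, gs)
        y = x * (g[:, :, None, None] * gs)
        return y[0] if squeeze else y

    def backward(self, dout):
        if self._cache is None:
            return dout * (self.gate_override or 1.0)
        x, pre, g, u_pre, gs = self._cache
        c, h, w = x.shape[1], x.shape[2], x.shape[3]
        gate = g[:, :, None, None] * gs
        dx = dout * gate
        dgate = dout * x
        dg = (dgate * gs).sum(axis=(2, 3))
        dgs = (dgate * g[:, :, None, None]).sum(axis=1, keepdims=True)
        # spatial branch
        dv = dgs * gs * (1.0 - gs)
        du = self.conv2.backward(dv)
        du = np.where(u_pre > 0, du, 0.0)
        dm = self.conv1.backward(du)
        dx += dm / c
        # channel branch
        da = dg * g * (1.0 - g)
        dh = self.fc2.backward(da)
        dpre = np.where(pre > 0, dh, 0.0)
        ds = self.fc1.backward(dpre)
        dx += ds[:, :, None, None] / (h * w)
        return dx


def make_block(cfg: AttentionConfig, rng: np.random.Generator | None = None) -> Module:
    """Instantiate a seeded attention block from its configuration."""
    if cfg.kind == "se":
        return SEBlock(cfg.channels, cfg.reduction, rng=rng)
    if cfg.kind == "cbam":
        return CBAMBlock(cfg.channels, cfg.reduction, cfg.spatial_kernel, rng=rng)
    return PCSEMBlock(cfg.channels, cfg.reduction, cfg.spatial_kernel,
                      cfg.pcsem_mid_channels, rng=rng)


def se_forward(x: np.ndarray, cfg: AttentionConfig, block: Module | None = None,
               seed: int = 0) -> np.ndarray:
    """Apply an SE block (fresh seeded weights unless ``block`` is given)."""
    if cfg.kind != "se":
        raise ValueError("config kind must be 'se'")
    block = block or make_block(cfg, np.random.default_rng(seed))
    return block.forward(x)


def cbam_forward(x: np.ndarray, cfg: AttentionConfig, block: Module | None = None,
                 seed: int = 0) -> np.ndarray:
    if cfg.kind != "cbam":
        raise ValueError("config kind must be 'cbam'")
    block = block or make_block(cfg, np.random.default_rng(seed))
    return block.forward(x)


def pcsem_forward(x: np.ndarray, cfg: AttentionConfig, block: Module | None = None,
                  seed: int = 0) -> np.ndarray:
    if cfg.kind != "pcsem":
        raise ValueError("config kind must be 'pcsem'")
    block = block or make_block(cfg, np.random.default_rng(seed))
    return block.forward(x)


def block_param_count(cfg: AttentionConfig) -> int:
    """Closed-form learnable-scalar count of one attention block.

    The channel MLP (shared by all kinds) costs ``2*C*m + m + C`` with
    ``m = max(C // R, 1)`` (weights of both FCs plus both bias vectors).
    CBAM adds its 7×7 two-plane spatial convolution, P-CSEM its pair of 3×3
    excite/squeeze convolutions; all convolutions carry biases.
    """
    c, m = cfg.channels, cfg.bottleneck
    count = 2 * c * m + m + c
    k = cfg.spatial_kernel
    if cfg.kind == "cbam":
        count += k * k * 2 * 1 + 1
    elif cfg.kind == "pcsem":
        mid = cfg.pcsem_mid_channels
        count += (k * k * 1 * mid + mid) + (k * k * mid * 1 + 1)
    return count
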