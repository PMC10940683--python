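"""Dimension Information Embedding Attention (DIEA) and the Coordinate Attention baseline.

DIEA compresses a C×H×W feature map into four directional strip descriptors
(average and max pooling along each spatial axis), fuses them through a shared
squeeze 1×1 convolution, re-expands two directional embeddings, forms their
per-channel outer product — a C×(H+W)×(H+W) map whose four quadrants carry the
avg×avg, avg×max, max×avg and max×max axis interactions — and downsamples that
map with a stride-2 3×3 convolution into a sigmoid gate the same size as the
input.  Coordinate Attention (CA) is the ancestor design: average pooling
only, and a separable gate g[c,i,j] = g_h[c,i]·g_w[c,j].

Two routes are provided on purpose:

* ``DIEA``/``CoordinateAttention`` — trainable modules on the autodiff core,
  used inside classifiers;
* the plain-NumPy functions (``strip_avg_pool`` … ``gate_and_apply``,
  ``diea_forward``) — a forward-only reference path over unbatched C×H×W
  arrays, convenient for inspection and for cross-checking the modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import nn
from .autodiff import Tensor, concat

__all__ = [
    "PoolMode", "GateResize", "DownsampleGrouping", "DIEAConfig",
    "StripDescriptors", "ConcatDescriptor", "FusedDescriptor",
    "DirectionalEmbeddings", "EmbeddingMap", "AttentionGate",
    "strip_avg_pool", "strip_max_pool", "concat_strips", "h_swish",
    "fuse_descriptors", "split_and_expand", "outer_embed", "gate_and_apply",
    "diea_forward", "ca_forward", "DIEA", "CoordinateAttention",
]


class PoolMode(str, Enum):
    """Which pooling pair feeds the two descriptor branches.

    AP_MP is the published operator (average + max); AP_AP and MP_MP are the
    ablation variants in which both branches use the same pooling.
    """

    AP_MP = "ap_mp"
    AP_AP = "ap_ap"
    MP_MP = "mp_mp"


class GateResize(str, Enum):
    REQUIRE_SQUARE = "require_square"
    BILINEAR = "bilinear"


class DownsampleGrouping(str, Enum):
    DEPTHWISE = "depthwise"
    FULL = "full"
    GROUPED = "grouped"


@dataclass
class DIEAConfig:
    """Hyper-parameters of the attention operator.

    reduction follows the SE/CA squeeze convention: the fused descriptor has
    max(min_mid_channels, channels // reduction) channels.  The stride-2 3×3
    downsampling convolution is depthwise by default, which keeps the added
    parameter and MAC budget negligible next to any backbone.
    """

    channels: int
    reduction: int = 32
    min_mid_channels: int = 8
    pool_mode: PoolMode = PoolMode.AP_MP
    downsample_grouping: DownsampleGrouping = DownsampleGrouping.DEPTHWISE
    downsample_groups: int = 1          # used when downsample_grouping == GROUPED
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    gate_resize: GateResize = GateResize.REQUIRE_SQUARE

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.mid_channels < 1:
            raise ValueError(f"floor(channels/reduction) with floor {self.min_mid_channels} "
                             "must leave at least one mid channel")

    @property
    def mid_channels(self) -> int:
        return max(self.min_mid_channels, self.channels // self.reduction)


# --------------------------------------------------------------------------
# descriptor containers
# --------------------------------------------------------------------------

def _check_chw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or min(x.shape) < 1:
        raise ValueError(f"expected a C×H×W array with positive sizes, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite entries")
    return x


@dataclass
class StripDescriptors:
    """The four 1-D pooled tensors: a_h,m_h are C×H; a_w,m_w are C×W."""

    a_h: np.ndarray
    a_w: np.ndarray
    m_h: np.ndarray
    m_w: np.ndarray

    def __post_init__(self):
        if self.a_h.shape != self.m_h.shape or self.a_w.shape != self.m_w.shape \
                or self.a_h.shape[0] != self.a_w.shape[0]:
            raise ValueError("inconsistent strip descriptor shapes")


@dataclass
class ConcatDescriptor:
    """Spliced descriptors: a = [a_h ; a_w^T], m = [m_h ; m_w^T], both C×(H+W)."""

    a: np.ndarray
    m: np.ndarray
    split_h: int                       # index separating the H part from the W part

    def __post_init__(self):
        if self.a.shape != self.m.shape:
            raise ValueError("a and m must have equal shapes")
        if not 0 < self.split_h < self.a.shape[1]:
            raise ValueError("split index must lie strictly inside the spliced axis")


@dataclass
class FusedDescriptor:
    h: np.ndarray                      # mid×(2H+2W)
    split_hw: int                      # = H+W

    def __post_init__(self):
        if self.h.shape[1] != 2 * self.split_hw:
            raise ValueError("fused length must be exactly 2(H+W)")


@dataclass
class DirectionalEmbeddings:
    h_a: np.ndarray                    # C×(H+W)×1
    h_m: np.ndarray                    # C×1×(H+W)

    def __post_init__(self):
        if self.h_a.ndim != 3 or self.h_a.shape[2] != 1:
            raise ValueError(f"h_a must be C×(H+W)×1, got {self.h_a.shape}")
        if self.h_m.ndim != 3 or self.h_m.shape[1] != 1:
            raise ValueError(f"h_m must be C×1×(H+W), got {self.h_m.shape}")
        if self.h_a.shape[0] != self.h_m.shape[0] or self.h_a.shape[1] != self.h_m.shape[2]:
            raise ValueError("h_a and h_m disagree on C or H+W")


@dataclass
class EmbeddingMap:
    h_am: np.ndarray                   # C×(H+W)×(H+W); rank <= 1 per channel


@dataclass
class AttentionGate:
    g: np.ndarray                      # C×H×W, entries strictly in (0,1)


# --------------------------------------------------------------------------
# functional reference path (NumPy, unbatched)
# --------------------------------------------------------------------------

def strip_avg_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strip average pooling: a_h[c,h] = mean_i x[c,h,i]; a_w[c,w] = mean_j x[c,j,w]."""
    x = _check_chw(x)
    return x.mean(axis=2), x.mean(axis=1)


def strip_max_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strip max pooling: m_h[c,h] = max_i x[c,h,i]; m_w[c,w] = max_j x[c,j,w]."""
    x = _check_chw(x)
    return x.max(axis=2), x.max(axis=1)


def concat_strips(sd: StripDescriptors) -> ConcatDescriptor:
    """Splice each pooling pair into one C×(H+W) descriptor (h part first)."""
    return ConcatDescriptor(a=np.concatenate([sd.a_h, sd.a_w], axis=1),
                            m=np.concatenate([sd.m_h, sd.m_w], axis=1),
                            split_h=sd.a_h.shape[1])


def h_swish(t: np.ndarray) -> np.ndarray:
    """Hard swish: x * clip(x+3, 0, 6) / 6."""
    t = np.asarray(t, dtype=float)
    return t * np.clip(t + 3.0, 0.0, 6.0) / 6.0


def _bn_eval(x: np.ndarray, bn: nn.BatchNorm2d, ch_axis: int = 0) -> np.ndarray:
    """Inference-mode batch norm with the layer's running statistics."""
    shape = [1] * x.ndim
    shape[ch_axis] = -1
    mu = bn.running_mean.reshape(shape).astype(float)
    var = bn.running_var.reshape(shape).astype(float)
    w = bn.weight.data.reshape(shape).astype(float)
    b = bn.bias.data.reshape(shape).astype(float)
    return (x - mu) / np.sqrt(var + bn.eps) * w + b


def fuse_descriptors(cd: ConcatDescriptor, module: "DIEA") -> FusedDescriptor:
    """Squeeze [a;m] (length 2H+2W) through F1 (1×1 conv C→mid), BN and h_swish."""
    s = np.concatenate([cd.a, cd.m], axis=1)                   # C×(2H+2W)
    w1 = module.f1.weight.data[:, :, 0, 0].astype(float)        # mid×C
    h = _bn_eval(w1 @ s, module.bn1)
    return FusedDescriptor(h=h_swish(h), split_hw=cd.a.shape[1])


def split_and_expand(fd: FusedDescriptor, module: "DIEA") -> DirectionalEmbeddings:
    """Slice the fused descriptor at H+W and restore both halves to C channels.

    The first half goes through F2 to become the column embedding h_a
    (C×(H+W)×1); the second half is transposed first, then F3 makes the row
    embedding h_m (C×1×(H+W)).
    """
    k = fd.split_hw
    if fd.h.shape[1] != 2 * k:
        raise ValueError("fused descriptor length must be exactly 2(H+W)")
    w2 = module.f2.weight.data[:, :, 0, 0].astype(float)        # C×mid
    w3 = module.f3.weight.data[:, :, 0, 0].astype(float)
    h_a = _bn_eval(w2 @ fd.h[:, :k], module.bn2)[:, :, None]    # C×(H+W)×1
    h_m = _bn_eval(w3 @ fd.h[:, k:], module.bn3)[:, None, :]    # C×1×(H+W)
    return DirectionalEmbeddings(h_a=h_a, h_m=h_m)


def outer_embed(de: DirectionalEmbeddings) -> EmbeddingMap:
    """Per-channel outer product h_am[c] = h_a[c] · h_m[c] (rank <= 1 per channel)."""
    return EmbeddingMap(h_am=de.h_a * de.h_m)


def _conv2d_np(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
               stride: int, padding: int, groups: int) -> np.ndarray:
    """Plain single-image conv used only by the reference path."""
    C, H, W = x.shape
    co, cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    ho = (H + 2 * padding - kh) // stride + 1
    wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((co, ho, wo))
    cpg_out = co // groups
    for o in range(co):
        g = o // cpg_out
        for i in range(ho):
            for j in range(wo):
                patch = xp[g * cg:(g + 1) * cg, i * stride:i * stride + kh,
                           j * stride:j * stride + kw]
                out[o, i, j] = float((patch * w[o]).sum())
    if b is not None:
        out += b[:, None, None]
    return out


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (half-pixel-centre convention)."""
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - t
        m[i, hi_c] += t
    return m


def gate_and_apply(x: np.ndarray, em: EmbeddingMap,
                   module: "DIEA") -> tuple[np.ndarray, AttentionGate]:
    """Downsample the embedding map with F↓ (3×3, stride 2, padding 1), squash
    through a sigmoid and gate the input multiplicatively."""
    x = _check_chw(x)
    C, H, W = x.shape
    cfg = module.cfg
    if H != W and cfg.gate_resize is GateResize.REQUIRE_SQUARE:
        raise ValueError(
            f"input is {H}×{W}: the stride-2 downsampling only recovers the input "
            "size for square maps; set gate_resize=GateResize.BILINEAR to allow "
            "non-square inputs")
    pre = _conv2d_np(em.h_am, module.f_down.weight.data.astype(float),
                     module.f_down.bias.data.astype(float),
                     stride=2, padding=1, groups=module.f_down.groups)
    if pre.shape[1:] != (H, W):
        rh = _interp_matrix(H, pre.shape[1])
        rw = _interp_matrix(W, pre.shape[2])
        pre = np.einsum("hi,ciw,wj->chj", rh, pre, rw.T)
    g = 1.0 / (1.0 + np.exp(-pre))
    return x * g, AttentionGate(g=g)


def diea_forward(x: np.ndarray, module: "DIEA") -> np.ndarray:
    """Full forward of the attention operator on one C×H×W array via the
    NumPy reference path (inference-mode batch norm)."""
    x = _check_chw(x)
    cfg = module.cfg
    avg = strip_avg_pool(x)
    mx = strip_max_pool(x)
    a_h, a_w = (mx if cfg.pool_mode is PoolMode.MP_MP else avg)
    m_h, m_w = (avg if cfg.pool_mode is PoolMode.AP_AP else mx)
    sd = StripDescriptors(a_h=a_h, a_w=a_w, m_h=m_h, m_w=m_w)
    cd = concat_strips(sd)
    fd = fuse_descriptors(cd, module)
    de = split_and_expand(fd, module)
    em = outer_embed(de)
    y, _ = gate_and_apply(x, em, module)
    return y


def ca_forward(x: np.ndarray, module: "CoordinateAttention") -> np.ndarray:
    """NumPy reference forward of Coordinate Attention on one C×H×W array."""
    x = _check_chw(x)
    a_h, a_w = strip_avg_pool(x)                                 # C×H, C×W
    s = np.concatenate([a_h, a_w], axis=1)                       # C×(H+W)
    w1 = module.f1.weight.data[:, :, 0, 0].astype(float)
    h = h_swish(_bn_eval(w1 @ s, module.bn1))
    H = a_h.shape[1]
    wh = module.conv_h.weight.data[:, :, 0, 0].astype(float)
    ww = module.conv_w.weight.data[:, :, 0, 0].astype(float)
    zh = wh @ h[:, :H] + module.conv_h.bias.data[:, None].astype(float)
    zw = ww @ h[:, H:] + module.conv_w.bias.data[:, None].astype(float)
    g_h = 1.0 / (1.0 + np.exp(-zh))                              # C×H
    g_w = 1.0 / (1.0 + np.exp(-zw))                              # C×W
    return x * g_h[:, :, None] * g_w[:, None, :]


# --------------------------------------------------------------------------
# trainable modules
# --------------------------------------------------------------------------

class DIEA(nn.Module):
    """The trainable attention operator (NCHW batches).

    1×1 convolutions are bias-free (each is followed by batch norm); the
    downsampling convolution carries a bias.  The gate of the most recent
    forward is kept on ``self.last_gate`` for inspection.
    """

    def __init__(self, cfg: DIEAConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c, mid = cfg.channels, cfg.mid_channels
        bn = dict(eps=cfg.bn_eps, momentum=cfg.bn_momentum)
        self.f1 = nn.Conv2d(c, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid, **bn)
        self.act = nn.HSwish()
        self.f2 = nn.Conv2d(mid, c, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c, **bn)
        self.f3 = nn.Conv2d(mid, c, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(c, **bn)
        groups = {DownsampleGrouping.DEPTHWISE: c,
                  DownsampleGrouping.FULL: 1,
                  DownsampleGrouping.GROUPED: cfg.downsample_groups}[cfg.downsample_grouping]
        self.f_down = nn.Conv2d(c, c, 3, stride=2, padding=1, groups=groups,
                                bias=True, rng=rng)
        self.last_gate: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, c, H, W = x.data.shape
        cfg = self.cfg
        if H != W and cfg.gate_resize is GateResize.REQUIRE_SQUARE:
            raise ValueError(
                f"input is {H}×{W}: set gate_resize=GateResize.BILINEAR for "
                "non-square feature maps")
        if cfg.pool_mode is PoolMode.MP_MP:
            a_h, a_w = x.max(axis=3), x.max(axis=2)
        else:
            a_h, a_w = x.mean(axis=3), x.mean(axis=2)
        if cfg.pool_mode is PoolMode.AP_AP:
            m_h, m_w = x.mean(axis=3), x.mean(axis=2)
        else:
            m_h, m_w = x.max(axis=3), x.max(axis=2)
        a = concat([a_h, a_w], axis=2)                           # N,C,H+W
        m = concat([m_h, m_w], axis=2)
        s = concat([a, m], axis=2).reshape(n, c, 2 * (H + W), 1)
        h = self.act(self.bn1(self.f1(s)))                       # N,mid,2(H+W),1
        k = H + W
        h_a = self.bn2(self.f2(h[:, :, :k, :]))                  # N,C,H+W,1
        h_m = self.bn3(self.f3(h[:, :, k:, :].transpose(0, 1, 3, 2)))  # N,C,1,H+W
        h_am = h_a * h_m                                         # N,C,H+W,H+W
        pre = self.f_down(h_am)
        if pre.data.shape[2:] != (H, W):
            rh = Tensor(_interp_matrix(H, pre.data.shape[2]).astype(np.float32))
            rw = Tensor(_interp_matrix(W, pre.data.shape[3]).T.astype(np.float32))
            pre = rh @ pre @ rw
        g = pre.sigmoid()
        self.last_gate = g.data
        return x * g


class CoordinateAttention(nn.Module):
    """Coordinate Attention: average-pooled strips only, separable gate."""

    def __init__(self, channels: int, reduction: int = 32, min_mid_channels: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        mid = max(min_mid_channels, channels // reduction)
        self.f1 = nn.Conv2d(channels, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.act = nn.HSwish()
        self.conv_h = nn.Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.conv_w = nn.Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.last_gate: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, c, H, W = x.data.shape
        a_h = x.mean(axis=3).reshape(n, c, H, 1)
        a_w = x.mean(axis=2).reshape(n, c, W, 1)
        s = concat([a_h, a_w], axis=2)                           # N,C,H+W,1
        h = self.act(self.bn1(self.f1(s)))
        g_h = self.conv_h(h[:, :, :H, :]).sigmoid()              # N,C,H,1
        g_w = self.conv_w(h[:, :, H:, :].transpose(0, 1, 3, 2)).sigmoid()  # N,C,1,W
        self.last_gate = (g_h.data * g_w.data)
        return x * g_h * g_w
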