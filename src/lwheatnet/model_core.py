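"""LWheatNet architecture: stem, mixed attention, stacked inverted-residual
core layers and classification head.

The network is a ShuffleNet-V2-style lightweight classifier specialised for
5-class wheat-seed images.  Feature maps are NumPy arrays in NCHW layout (a
single map may be passed as CHW).  Three build variants exist:

``backbone``            the inverted-residual core only (WheatNet),
``backbone+tpsa``       plus two-path spatial attention,
``backbone+tpsa+eca``   plus efficient channel attention in parallel — the
                        full mixed-attention model (LWheatNet).

With the default configuration the variants count 1.26M / 1.33M / 1.33M
trainable parameters respectively.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Module, Sequential, Conv2d, DepthwiseConv2d, BatchNorm2d, ReLU, \
    MaxPool2d, GlobalAvgPool, Dropout, Linear, ChannelConv1d, softmax

__all__ = [
    "ConvSpec",
    "AttentionConfig",
    "ModelConfig",
    "ParamCount",
    "VARIANTS",
    "canonical_variant",
    "channel_split",
    "channel_shuffle",
    "depthwise_separable_conv",
    "DepthwiseSeparableConv",
    "eca_kernel_size",
    "ECAAttention",
    "TPSAAttention",
    "MixedAttention",
    "BasicUnit",
    "DownsamplingUnit",
    "CoreLayer",
    "LWheatNet",
    "build_model",
    "count_parameters",
    "format_param_count",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("backbone", "backbone+tpsa", "backbone+tpsa+eca")

_VARIANT_ALIASES = {
    "backbone": "backbone",
    "wheatnet": "backbone",
    "backbone+tpsa": "backbone+tpsa",
    "wheatnet+tpsa": "backbone+tpsa",
    "backbone+tpsa+eca": "backbone+tpsa+eca",
    "wheatnet+tpsa+eca": "backbone+tpsa+eca",
    "lwheatnet": "backbone+tpsa+eca",
}

PLACEMENTS = ("after-stem", "after-core-1", "after-core-2", "after-core-3")


def canonical_variant(name: str) -> str:
    """Resolve a variant name or alias (e.g. ``lwheatnet``) to its canonical
    form; raises ``ValueError`` for unknown names."""
    key = name.strip().lower()
    if key not in _VARIANT_ALIASES:
        raise ValueError(
            f"unknown variant {name!r}; expected one of {sorted(set(_VARIANT_ALIASES))}")
    return _VARIANT_ALIASES[key]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ConvSpec:
    """Description of a single convolution used by the unit structures."""

    kernel: int
    in_channels: int
    out_channels: int
    stride: int = 1
    depthwise: bool = False
    has_bias: bool = False
    followed_by_bn: bool = True
    activation: str = "none"

    def __post_init__(self):
        if self.kernel not in (1, 3, 5):
            raise ValueError(f"kernel must be 1, 3 or 5, got {self.kernel}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.depthwise and self.in_channels != self.out_channels:
            raise ValueError("depthwise convolution requires in_channels == out_channels")
        if self.activation not in ("none", "relu", "sigmoid"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class AttentionConfig:
    """Mixed-attention hyperparameters.

    ``eca_gamma``/``eca_b`` are the constants of the adaptive 1-D kernel-size
    rule (2 and 1); ``tpsa_reduction`` shrinks the channel descriptor to
    ``C // reduction`` (floored, minimum 1); ``tpsa_kernels`` are the two
    parallel multi-scale kernels (3 and 5).  ``placements`` lists where mixed
    attention is inserted; the default (after core layers 2 and 3) is the
    configuration that realises the published 1.33M parameter total.  Setting
    ``spatial_tpsa`` applies the two-path convolutions to the reduced
    full-resolution map (an H x W mask) instead of the pooled descriptor;
    parameter counts are identical either way.
    """

    eca_gamma: float = 2.0
    eca_b: float = 1.0
    tpsa_reduction: int = 16
    tpsa_kernels: tuple[int, int] = (3, 5)
    placements: tuple[str, ...] = ("after-core-2", "after-core-3")
    spatial_tpsa: bool = False

    def __post_init__(self):
        if self.eca_gamma <= 0:
            raise ValueError("eca_gamma must be positive")
        if self.tpsa_reduction < 1:
            raise ValueError("tpsa_reduction must be >= 1")
        if any(k % 2 == 0 for k in self.tpsa_kernels):
            raise ValueError("tpsa kernels must be odd")
        self.tpsa_kernels = tuple(int(k) for k in self.tpsa_kernels)
        self.placements = tuple(self.placements)
        for p in self.placements:
            if p not in PLACEMENTS:
                raise ValueError(f"unknown placement {p!r}; expected one of {PLACEMENTS}")


@dataclass
class ModelConfig:
    """Full architectural description.

    Defaults reproduce the published model: 224x224x3 input, 24-channel stem,
    stage widths (116, 232, 464) with (3, 7, 3) basic units per core layer
    (the ShuffleNet-V2-1.0x layout), a 1024-channel head and 5 classes.
    """

    input_size: int = 224
    stem_channels: int = 24
    stage_channels: tuple[int, int, int] = (116, 232, 464)
    stage_repeats: tuple[int, int, int] = (3, 7, 3)
    head_channels: int = 1024
    num_classes: int = 5
    dropout_p: float = 0.4
    variant: str = "backbone+tpsa+eca"
    seed: int = 0
    attention: AttentionConfig = field(default_factory=AttentionConfig)

    def __post_init__(self):
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        self.stage_repeats = tuple(int(r) for r in self.stage_repeats)
        if any(c % 2 for c in self.stage_channels):
            raise ValueError("stage channels must be even (channel split halves them)")
        if any(r < 1 for r in self.stage_repeats):
            raise ValueError("stage repeats must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        self.variant = canonical_variant(self.variant)
        if isinstance(self.attention, dict):
            self.attention = AttentionConfig(**self.attention)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["stage_repeats"] = list(self.stage_repeats)
        d["attention"]["tpsa_kernels"] = list(self.attention.tpsa_kernels)
        d["attention"]["placements"] = list(self.attention.placements)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "attention" in d and isinstance(d["attention"], dict):
            d["attention"] = AttentionConfig(**d["attention"])
        return cls(**d)


@dataclass
class ParamCount:
    """Trainable-parameter census: grand total and per named block."""

    total: int
    per_block: dict[str, int]

    def __post_init__(self):
        if self.total != sum(self.per_block.values()):
            raise ValueError("total must equal the sum of per-block counts")

    @property
    def millions(self) -> float:
        return round(self.total / 1e6, 2)


def format_param_count(total: int) -> str:
    """Format a raw count the way model-size tables print it, e.g. ``1.26M``."""
    return f"{total / 1e6:.2f}M"


# ---------------------------------------------------------------------------
# Channel plumbing
# ---------------------------------------------------------------------------


def _channel_axis(x: np.ndarray) -> int:
    if x.ndim == 4:
        return 1
    if x.ndim == 3:
        return 0
    raise ValueError(f"expected a CHW or NCHW array, got ndim={x.ndim}")


def channel_split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature map into its leading and trailing channel halves."""
    ax = _channel_axis(x)
    c = x.shape[ax]
    if c % 2:
        raise ValueError(f"channel split requires an even channel count, got {c}")
    h = c // 2
    first = np.take(x, range(0, h), axis=ax)
    second = np.take(x, range(h, c), axis=ax)
    return first, second


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Reorder channels by reshape-to-(groups, C/groups) and transpose.

    With ``groups`` branches concatenated, this interleaves their channels so
    the next split sees a mix of both.  It is a pure permutation; applying
    ``channel_shuffle(y, C // groups)`` inverts it.
    """
    ax = _channel_axis(x)
    c = x.shape[ax]
    if groups < 1 or c % groups:
        raise ValueError(f"channel count {c} not divisible by groups={groups}")
    perm_shape = list(x.shape)
    perm_shape[ax:ax + 1] = [groups, c // groups]
    y = x.reshape(perm_shape)
    y = np.swapaxes(y, ax, ax + 1)
    return np.ascontiguousarray(y.reshape(x.shape))


# ---------------------------------------------------------------------------
# Depthwise-separable convolution
# ---------------------------------------------------------------------------


class DepthwiseSeparableConv(Module):
    """Depthwise k x k convolution followed by a 1x1 pointwise convolution.

    Parameter cost is k^2 * C for the spatial stage plus C * C_out for the
    channel-mixing stage (plus biases if requested) — the factorisation that
    makes the network lightweight.
    """

    def __init__(self, spec: ConvSpec, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        self.depthwise = DepthwiseConv2d(spec.in_channels, spec.kernel, spec.stride, rng=rng)
        self.pointwise = Conv2d(spec.in_channels, spec.out_channels, 1,
                                bias=spec.has_bias, rng=rng)

    def forward(self, x, train: bool = False):
        return self.pointwise.forward(self.depthwise.forward(x, train), train)

    def backward(self, dy):
        return self.depthwise.backward(self.pointwise.backward(dy))


def depthwise_separable_conv(x: np.ndarray, spec: ConvSpec,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialised depthwise-separable convolution to ``x``.

    A shape/contract helper: builds the two-stage convolution described by
    ``spec`` (seeded) and runs it once.
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    y = DepthwiseSeparableConv(spec, rng=rng).forward(x)
    return y[0] if squeeze else y


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel size for efficient channel attention.

    k = |log2(C)/gamma + b/gamma|_odd — the odd integer nearest to the
    interaction range implied by the channel count; ties round up (the larger
    receptive field) and the result is clamped to >= 1.
    """
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = math.log2(channels) / gamma + b / gamma
    lower = 2 * math.floor((t - 1) / 2) + 1
    upper = lower + 2
    k = upper if (t - lower) >= (upper - t) else lower
    return max(1, k)


class ECAAttention(Module):
    """Efficient channel attention: per-channel gating from a 1-D convolution
    over the globally pooled channel descriptor.

    The descriptor y_c = mean_{i,j} x_{c,i,j} is convolved across the channel
    axis with an adaptive odd kernel (shared weights, no bias), squashed
    through a sigmoid, and broadcast-multiplied back onto the input.
    """

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0,
                 dtype=np.float32):
        self.channels = channels
        self.kernel = eca_kernel_size(channels, gamma, b)
        self.conv = ChannelConv1d(self.kernel, dtype=dtype)

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        s = x.mean(axis=(2, 3))
        z = self.conv.forward(s, train)
        a = 1.0 / (1.0 + np.exp(-z))
        self._cache = (x, a, h, w)
        return x * a[:, :, None, None]

    def backward(self, dy):
        x, a, h, w = self._cache
        dx = dy * a[:, :, None, None]
        da = (dy * x).sum(axis=(2, 3))
        dz = da * a * (1.0 - a)
        ds = self.conv.backward(dz)
        dx += ds[:, :, None, None] / (h * w)
        return dx


class TPSAAttention(Module):
    """Two-path spatial attention.

    The input is globally average-pooled to a 1x1xC descriptor, reduced to
    max(1, C // reduction) channels by a 1x1 convolution, passed through two
    parallel convolutions of different scales (3x3 and 5x5, same padding)
    whose outputs are summed, expanded back to C channels, sigmoid-activated
    and broadcast-multiplied onto the input.  All four convolutions carry
    biases.  With ``spatial=True`` the reduction and two-path convolutions
    act on the full-resolution map instead, producing an H x W gate.
    """

    def __init__(self, channels: int, reduction: int = 16,
                 kernels: tuple[int, int] = (3, 5), spatial: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.reduced = max(1, channels // reduction)
        self.spatial = spatial
        r = self.reduced
        self.reduce = Conv2d(channels, r, 1, bias=True, rng=rng, dtype=dtype)
        self.path_a = Conv2d(r, r, kernels[0], bias=True, rng=rng, dtype=dtype)
        self.path_b = Conv2d(r, r, kernels[1], bias=True, rng=rng, dtype=dtype)
        self.expand = Conv2d(r, channels, 1, bias=True, rng=rng, dtype=dtype)

    def forward(self, x, train: bool = False):
        g = x if self.spatial else x.mean(axis=(2, 3), keepdims=True)
        t = self.reduce.forward(g, train)
        p = self.path_a.forward(t, train) + self.path_b.forward(t, train)
        e = self.expand.forward(p, train)
        a = 1.0 / (1.0 + np.exp(-e))
        self._cache = (x, a)
        return x * a

    def backward(self, dy):
        x, a = self._cache
        dx = dy * a
        da = dy * x
        if not self.spatial:
            da = da.sum(axis=(2, 3), keepdims=True)
        de = da * a * (1.0 - a)
        dp = self.expand.backward(de)
        dt = self.path_a.backward(dp) + self.path_b.backward(dp)
        dg = self.reduce.backward(dt)
        if self.spatial:
            dx += dg
        else:
            h, w = x.shape[2], x.shape[3]
            dx += dg / (h * w)
        return dx


class MixedAttention(Module):
    """Parallel fusion of channel (ECA) and spatial (TPSA) attention.

    The two branches see the same input and their gated outputs are summed,
    so neither branch filters what the other one sees.  The active branches
    depend on the build variant: the backbone variant is an identity, the
    +tpsa variant applies TPSA alone, and the full variant returns
    eca(x) + tpsa(x).
    """

    def __init__(self, channels: int, cfg: AttentionConfig, variant: str,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        variant = canonical_variant(variant)
        self.variant = variant
        self.channels = channels
        self.eca = None
        self.tpsa = None
        if variant in ("backbone+tpsa", "backbone+tpsa+eca"):
            self.tpsa = TPSAAttention(channels, cfg.tpsa_reduction, cfg.tpsa_kernels,
                                      spatial=cfg.spatial_tpsa, rng=rng, dtype=dtype)
        if variant == "backbone+tpsa+eca":
            self.eca = ECAAttention(channels, cfg.eca_gamma, cfg.eca_b, dtype=dtype)

    def forward(self, x, train: bool = False):
        if self.variant == "backbone":
            return x
        if self.variant == "backbone+tpsa":
            return self.tpsa.forward(x, train)
        return self.eca.forward(x, train) + self.tpsa.forward(x, train)

    def backward(self, dy):
        if self.variant == "backbone":
            return dy
        if self.variant == "backbone+tpsa":
            return self.tpsa.backward(dy)
        return self.eca.backward(dy) + self.tpsa.backward(dy)


def mam(x: np.ndarray, cfg: AttentionConfig, variant: str,
        rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialised mixed-attention module to ``x`` (contract
    helper mirroring :func:`depthwise_separable_conv`)."""
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    module = MixedAttention(x.shape[1], cfg, variant, rng=rng)
    y = module.forward(x)
    return y[0] if squeeze else y


# ---------------------------------------------------------------------------
# Inverted-residual units
# ---------------------------------------------------------------------------


class BasicUnit(Module):
    """Stride-1 unit: channel split, an untouched left branch, a
    1x1 conv / 3x3 depthwise / 1x1 conv right branch (each followed by BN,
    ReLU on the pointwise stages), concatenation and a 2-group channel
    shuffle.  All three convolutions preserve the branch width, so the unit
    preserves shape."""

    def __init__(self, width: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if width % 2:
            raise ValueError(f"basic unit width must be even, got {width}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.width = width
        h = width // 2
        self.branch = Sequential(
            Conv2d(h, h, 1, rng=rng, dtype=dtype), BatchNorm2d(h, dtype=dtype), ReLU(),
            DepthwiseConv2d(h, 3, 1, rng=rng, dtype=dtype), BatchNorm2d(h, dtype=dtype),
            Conv2d(h, h, 1, rng=rng, dtype=dtype), BatchNorm2d(h, dtype=dtype), ReLU(),
        )

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.width:
            raise ValueError(f"expected {self.width} channels, got {x.shape[1]}")
        left, right = channel_split(x)
        right = self.branch.forward(right, train)
        return channel_shuffle(np.concatenate([left, right], axis=1), 2)

    def backward(self, dy):
        c = dy.shape[1]
        d = channel_shuffle(dy, c // 2)  # inverse of the 2-group shuffle
        h = c // 2
        dleft, dright = d[:, :h], d[:, h:]
        dright = self.branch.backward(dright)
        return np.concatenate([dleft, dright], axis=1)


class DownsamplingUnit(Module):
    """Stride-2 unit: no channel split — both branches consume the full
    input.  Left: 3x3 depthwise (stride 2) + BN, then 1x1 conv + BN + ReLU.
    Right: the basic-unit branch with its depthwise stage at stride 2.  Each
    branch emits out_width/2 channels; concatenation and a 2-group shuffle
    yield out_width channels at half the spatial resolution."""

    def __init__(self, in_channels: int, out_width: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if out_width % 2:
            raise ValueError(f"downsampling out_width must be even, got {out_width}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_width = out_width
        h = out_width // 2
        self.left = Sequential(
            DepthwiseConv2d(in_channels, 3, 2, rng=rng, dtype=dtype),
            BatchNorm2d(in_channels, dtype=dtype),
            Conv2d(in_channels, h, 1, rng=rng, dtype=dtype), BatchNorm2d(h, dtype=dtype),
            ReLU(),
        )
        self.right = Sequential(
            Conv2d(in_channels, h, 1, rng=rng, dtype=dtype), BatchNorm2d(h, dtype=dtype),
            ReLU(),
            DepthwiseConv2d(h, 3, 2, rng=rng, dtype=dtype), BatchNorm2d(h, dtype=dtype),
            Conv2d(h, h, 1, rng=rng, dtype=dtype), BatchNorm2d(h, dtype=dtype), ReLU(),
        )

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        left = self.left.forward(x, train)
        right = self.right.forward(x, train)
        return channel_shuffle(np.concatenate([left, right], axis=1), 2)

    def backward(self, dy):
        c = dy.shape[1]
        d = channel_shuffle(dy, c // 2)
        h = c // 2
        return self.left.backward(d[:, :h]) + self.right.backward(d[:, h:])


def basic_unit(x: np.ndarray, width: int,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialised basic unit (contract helper)."""
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    y = BasicUnit(width, rng=rng).forward(x)
    return y[0] if squeeze else y


def downsampling_unit(x: np.ndarray, out_width: int,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialised downsampling unit (contract helper)."""
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    y = DownsamplingUnit(x.shape[1], out_width, rng=rng).forward(x)
    return y[0] if squeeze else y


class CoreLayer(Sequential):
    """One downsampling unit followed by ``repeats`` basic units: halves the
    spatial resolution once and sets the channel width of the stage."""

    def __init__(self, in_channels: int, out_width: int, repeats: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {repeats}")
        units = [DownsamplingUnit(in_channels, out_width, rng=rng, dtype=dtype)]
        units += [BasicUnit(out_width, rng=rng, dtype=dtype) for _ in range(repeats)]
        super().__init__(*units)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------


class LWheatNet(Module):
    """The assembled classifier.

    stem (3x3 stride-2 conv -> BN -> ReLU) -> 3x3 stride-2 max pool ->
    [mixed attention at configured placements] -> core layers 1-3 ->
    1x1 conv to head_channels (BN, ReLU) -> global average pool -> dropout ->
    fully connected logits.  ``predict_proba`` applies the softmax.
    """

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        rng = np.random.default_rng(cfg.seed)
        self.config = cfg
        a = cfg.attention
        self.stem = Sequential(
            Conv2d(3, cfg.stem_channels, 3, stride=2, rng=rng, dtype=dtype),
            BatchNorm2d(cfg.stem_channels, dtype=dtype), ReLU(),
        )
        self.pool = MaxPool2d(3, 2, 1)

        def attn_at(placement: str, channels: int):
            if cfg.variant != "backbone" and placement in a.placements:
                return MixedAttention(channels, a, cfg.variant, rng=rng, dtype=dtype)
            return None

        c1, c2, c3 = cfg.stage_channels
        r1, r2, r3 = cfg.stage_repeats
        self.mam_after_stem = attn_at("after-stem", cfg.stem_channels)
        self.core1 = CoreLayer(cfg.stem_channels, c1, r1, rng=rng, dtype=dtype)
        self.mam_after_core_1 = attn_at("after-core-1", c1)
        self.core2 = CoreLayer(c1, c2, r2, rng=rng, dtype=dtype)
        self.mam_after_core_2 = attn_at("after-core-2", c2)
        self.core3 = CoreLayer(c2, c3, r3, rng=rng, dtype=dtype)
        self.mam_after_core_3 = attn_at("after-core-3", c3)
        self.head = Sequential(
            Conv2d(c3, cfg.head_channels, 1, rng=rng, dtype=dtype),
            BatchNorm2d(cfg.head_channels, dtype=dtype), ReLU(),
        )
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(cfg.dropout_p)
        self.fc = Linear(cfg.head_channels, cfg.num_classes, bias=True, rng=rng,
                         dtype=dtype)

    # stages in execution order, attention interleaved
    def _stages(self):
        yield self.stem
        yield self.pool
        if self.mam_after_stem is not None:
            yield self.mam_after_stem
        yield self.core1
        if self.mam_after_core_1 is not None:
            yield self.mam_after_core_1
        yield self.core2
        if self.mam_after_core_2 is not None:
            yield self.mam_after_core_2
        yield self.core3
        if self.mam_after_core_3 is not None:
            yield self.mam_after_core_3
        yield self.head
        yield self.gap
        yield self.dropout
        yield self.fc

    def forward(self, x, train: bool = False):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got shape {x.shape}")
        for stage in self._stages():
            x = stage.forward(x, train)
        return x

    def backward(self, dlogits):
        dy = dlogits
        for stage in reversed(list(self._stages())):
            dy = stage.backward(dy)
        return dy

    def attach_rng(self, rng: np.random.Generator) -> None:
        """Point the dropout layer at the training loop's RNG stream."""
        self.dropout.rng = rng

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class-probability predictions in evaluation mode (running BN
        statistics, no dropout)."""
        outs = [softmax(self.forward(x[i:i + batch_size]))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)


def build_model(cfg: ModelConfig | None = None, dtype=np.float32) -> LWheatNet:
    """Build the network described by ``cfg`` (defaults: the full
    mixed-attention variant at 224x224, 5 classes)."""
    return LWheatNet(cfg if cfg is not None else ModelConfig(), dtype=dtype)


def count_parameters(model: LWheatNet) -> ParamCount:
    """Exact census of trainable scalars (conv and FC weights/biases, BN
    scale and shift; running statistics are buffers, not parameters)."""
    blocks = [
        "stem", "mam_after_stem", "core1", "mam_after_core_1", "core2",
        "mam_after_core_2", "core3", "mam_after_core_3", "head", "fc",
    ]
    per_block: dict[str, int] = {}
    for name in blocks:
        module = getattr(model, name, None)
        if module is None:
            continue
        per_block[name] = sum(p.size for p in module.parameters())
    return ParamCount(total=sum(per_block.values()), per_block=per_block)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model: LWheatNet, path) -> None:
    """Serialise config + named parameter arrays + BN running statistics to a
    single ``.npz`` file."""
    arrays = {"param." + k: p.data for k, p in model.named_parameters()}
    arrays.update({"buffer." + k: v for k, v in model.named_buffers()})
    arrays["config"] = np.array(json.dumps(model.config.to_dict()))
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> LWheatNet:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path, allow_pickle=False) as npz:
        cfg = ModelConfig.from_dict(json.loads(str(npz["config"])))
        model = build_model(cfg)
        params = dict(model.named_parameters())
        for key in npz.files:
            if key.startswith("param."):
                name = key[len("param."):]
                params[name].data = npz[key].copy()
                params[name].grad = np.zeros_like(params[name].data)
        buffer_names = {k for k, _ in model.named_buffers()}
        for key in npz.files:
            if key.startswith("buffer."):
                name = key[len("buffer."):]
                if name not in buffer_names:
                    raise KeyError(f"unknown buffer {name!r} in checkpoint")
                _assign_buffer(model, name, npz[key].copy())
    return model


def _assign_buffer(model: Module, dotted: str, value: np.ndarray) -> None:
    parts = dotted.split(".")
    obj = model
    for part in parts[:-1]:
        if part.isdigit():
            obj = obj.layers[int(part)] if hasattr(obj, "layers") else obj[int(part)]
        else:
            obj = getattr(obj, part)
    setattr(obj, parts[-1], value)
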