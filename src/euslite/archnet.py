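"""Declarative construction of the lightweight EUS classifier family.

The canonical network is a stack of seven convolution units — each a valid
(no-padding, stride-1) convolution, batch normalization, ReLU and a 2x2
average pooling — followed by a single dropout + linear classifier.  The
architecture family spans depths 5/6/7 (codes A/B/C) crossed with final
channel widths 64/128/256/512 (codes 1-4); C3 is the canonical instance.

Everything here is exact integer arithmetic on shapes and parameter counts;
:func:`build_model` materializes a spec as a trainable network in the
``euslite.nn`` engine.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .errors import ConfigError, ShapeError

__all__ = [
    "ConvUnitSpec",
    "ArchitectureSpec",
    "LayerShape",
    "build_canonical",
    "build_family",
    "build_desk",
    "shape_chain",
    "count_parameters",
    "max_units",
    "build_model",
    "unit_tap_names",
    "spec_to_config",
    "spec_from_config",
]

#: kernel schedules per family depth; the 5/6-unit variants keep the large
#: 9x9 opening kernel and the canonical 3x3 tail.
KERNEL_SCHEDULES: dict[int, tuple[int, ...]] = {
    5: (9, 5, 5, 3, 3),
    6: (9, 5, 5, 5, 3, 3),
    7: (9, 5, 5, 5, 3, 3, 2),
}
DEPTH_CODES = {5: "A", 6: "B", 7: "C"}
WIDTH_CODES = {64: "1", 128: "2", 256: "3", 512: "4"}
FAMILY_WIDTHS = (64, 128, 256, 512)


@dataclass(frozen=True)
class ConvUnitSpec:
    """One convolution unit: conv (stride 1, no padding) -> BN -> ReLU -> avg pool."""

    name: str
    kernel_side: int
    in_channels: int
    out_channels: int
    stride: int = 1
    padding: int = 0
    has_batchnorm: bool = True
    pool_side: int = 2
    pool_stride: int = 2
    pool_kind: str = "average"

    def __post_init__(self):
        if self.kernel_side < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ConfigError(f"{self.name}: kernel and channel counts must be >= 1")
        if self.pool_kind != "average":
            raise ConfigError(f"{self.name}: only average pooling is supported")

    @property
    def conv_param_count(self) -> int:
        """Weights + bias of the convolution."""
        return self.kernel_side**2 * self.in_channels * self.out_channels + self.out_channels

    @property
    def batchnorm_param_count(self) -> int:
        """Affine scale + shift terms."""
        return 2 * self.out_channels if self.has_batchnorm else 0


@dataclass(frozen=True)
class ArchitectureSpec:
    units: tuple[ConvUnitSpec, ...]
    input_side: int = 360
    final_width: int = 256
    dropout_rate: float = 0.8
    classifier_out: int = 2
    family_code: str = "C3"

    @property
    def classifier_in(self) -> int:
        """The classifier always sees one feature per final channel (a global
        average pool bridges chains that do not end at spatial side 1)."""
        return self.units[-1].out_channels if self.units else 1

    @property
    def depth(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class LayerShape:
    name: str
    side_pre_pool: int
    side_post_pool: int
    channels: int
    conv_param_count: int
    batchnorm_param_count: int


def max_units(input_side: int) -> int:
    """Upper bound on the number of conv-pool units: floor(log2(input_side)),
    since every 2x2 pooling halves the spatial side."""
    if input_side < 2:
        raise ConfigError(f"input_side must be >= 2, got {input_side}")
    return int(math.floor(math.log2(input_side)))


def _channel_schedule(depth: int, final_width: int) -> list[int]:
    """32, 32, then doubling capped at final_width; the last unit is forced to
    final_width so the classifier input always equals the family width."""
    ch = [32, 32]
    while len(ch) < depth:
        ch.append(min(ch[-1] * 2, final_width))
    ch = ch[:depth]
    ch[-1] = final_width
    return ch


def _make_units(kernels: tuple[int, ...], channels: list[int],
                pools: tuple[int, ...] | None = None) -> tuple[ConvUnitSpec, ...]:
    units = []
    c_in = 1
    for i, (k, c_out) in enumerate(zip(kernels, channels), start=1):
        pool = pools[i - 1] if pools else 2
        units.append(
            ConvUnitSpec(name=f"Conv{i}", kernel_side=k, in_channels=c_in,
                         out_channels=c_out, pool_side=pool, pool_stride=pool)
        )
        c_in = c_out
    return tuple(units)


def shape_chain(spec: ArchitectureSpec) -> list[LayerShape]:
    """Walk the spatial arithmetic: side -> side - k + 1 (valid convolution),
    then floor(side / 2) for the 2x2 average pool.  Raises :class:`ShapeError`
    naming the first unit whose side becomes non-positive."""
    side = spec.input_side
    chain: list[LayerShape] = []
    for u in spec.units:
        pre = (side + 2 * u.padding - u.kernel_side) // u.stride + 1
        if pre < 1:
            raise ShapeError(
                f"unit {u.name}: convolution of kernel {u.kernel_side} on side {side} "
                f"gives non-positive output side {pre}"
            )
        post = pre // u.pool_stride if u.pool_side > 1 else pre
        if post < 1:
            raise ShapeError(f"unit {u.name}: pooling side {pre} gives empty output")
        chain.append(
            LayerShape(
                name=u.name,
                side_pre_pool=pre,
                side_post_pool=post,
                channels=u.out_channels,
                conv_param_count=u.conv_param_count,
                batchnorm_param_count=u.batchnorm_param_count,
            )
        )
        side = post
    return chain


def count_parameters(spec: ArchitectureSpec, include_batchnorm: bool = True) -> int:
    """Trainable parameter total: conv weights+biases (+ BN affine terms when
    ``include_batchnorm``) plus the linear classifier."""
    total = sum(u.conv_param_count for u in spec.units)
    if include_batchnorm:
        total += sum(u.batchnorm_param_count for u in spec.units)
    total += spec.classifier_in * spec.classifier_out + spec.classifier_out
    return total


def build_canonical(input_side: int = 360, dropout_rate: float = 0.8) -> ArchitectureSpec:
    """The validated 7-unit, 256-channel network (family code C3).

    Kernels (9,5,5,5,3,3,2), channels 1->32->32->64->128->256->256->256, each
    unit pooled 2x2; single 256->2 classifier behind dropout.
    """
    spec = ArchitectureSpec(
        units=_make_units(KERNEL_SCHEDULES[7], _channel_schedule(7, 256)),
        input_side=input_side,
        final_width=256,
        dropout_rate=dropout_rate,
        family_code="C3",
    )
    shape_chain(spec)  # validates; raises ShapeError naming the failing unit
    return spec


def _adapted_kernels(depth: int, input_side: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Shrink the canonical kernel schedule so the chain stays positive at
    small input sides (desk-scale runs); pooling is skipped once the side
    reaches 1.  Returns (kernels, pools)."""
    kernels, pools = [], []
    side = input_side
    for k in KERNEL_SCHEDULES[depth]:
        k_eff = min(k, side)  # a kernel can at most consume the full extent
        side = side - k_eff + 1
        pool = 2 if side >= 2 else 1
        side = side // 2 if pool == 2 else side
        kernels.append(k_eff)
        pools.append(pool)
    return tuple(kernels), tuple(pools)


def build_family(input_side: int = 360) -> list[ArchitectureSpec]:
    """The 12-member grid: depths 5/6/7 (A/B/C) x final widths 64/128/256/512
    (1-4).  At the canonical 360-px input the schedules are the canonical ones
    and C3 equals :func:`build_canonical`; at smaller inputs the kernel
    schedule is adapted so every chain stays valid."""
    specs = []
    for depth in (5, 6, 7):
        if input_side == 360:
            kernels, pools = KERNEL_SCHEDULES[depth], None
        else:
            kernels, pools = _adapted_kernels(depth, input_side)
        for width in FAMILY_WIDTHS:
            code = DEPTH_CODES[depth] + WIDTH_CODES[width]
            spec = ArchitectureSpec(
                units=_make_units(kernels, _channel_schedule(depth, width), pools),
                input_side=input_side,
                final_width=width,
                dropout_rate=0.8,
                family_code=code,
            )
            shape_chain(spec)
            specs.append(spec)
    return specs


DESK_KERNELS = {96: (9, 5, 5, 3, 2), 64: (9, 5, 5, 3)}


def build_desk(input_side: int = 96, final_width: int = 128,
               dropout_rate: float = 0.8) -> ArchitectureSpec:
    """Desk-scale sibling of the canonical network for small inputs.

    96 px: kernels (9,5,5,3,2); 64 px: kernels (9,5,5,3); both end at spatial
    side 1 like the canonical chain.
    """
    if input_side not in DESK_KERNELS:
        raise ConfigError(f"no desk schedule for input_side {input_side}; use 64 or 96")
    kernels = DESK_KERNELS[input_side]
    # lighter 16-channel stem than the family schedule: desk runs are CPU-bound
    channels = [16, 32, 64, 128, 256, 512][: len(kernels)]
    channels = [min(c, final_width) for c in channels]
    channels[-1] = final_width
    spec = ArchitectureSpec(
        units=_make_units(kernels, channels),
        input_side=input_side,
        final_width=final_width,
        dropout_rate=dropout_rate,
        family_code=f"desk{input_side}",
    )
    shape_chain(spec)
    return spec


# ---------------------------------------------------------------------------
# materialization in the nn engine
# ---------------------------------------------------------------------------

def unit_tap_names(spec: ArchitectureSpec) -> list[str]:
    """Tap points for saliency: the (post-pool) output of each conv unit."""
    return [f"Unit{i}" for i in range(1, spec.depth + 1)]


def build_model(spec: ArchitectureSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the spec as a trainable network.

    Layer taps named ``Unit1..UnitN`` sit on each unit's pooled output; the
    classifier is GAP -> dropout -> linear so its input width always equals
    the spec's final channel count.
    """
    shape_chain(spec)
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, nn.Module]] = []
    for i, u in enumerate(spec.units, start=1):
        conv = nn.Conv2d(u.in_channels, u.out_channels, u.kernel_side,
                         u.stride, u.padding, bias=True, rng=rng, name=f"conv{i}")
        if i == 1:
            conv.needs_input_grad = False  # nothing upstream to update
        layers.append((f"Conv{i}", conv))
        if u.has_batchnorm:
            layers.append((f"BN{i}", nn.BatchNorm2d(u.out_channels, name=f"bn{i}")))
        layers.append((f"ReLU{i}", nn.ReLU()))
        if u.pool_side > 1:
            layers.append((f"Unit{i}", nn.AvgPool2d(u.pool_side)))
        else:
            layers.append((f"Unit{i}", _Identity()))
    layers.append(("GAP", nn.GlobalAvgPool()))
    layers.append(("Dropout", nn.Dropout(spec.dropout_rate)))
    layers.append(("FC1", nn.Linear(spec.classifier_in, spec.classifier_out,
                                    rng=rng, name="fc1")))
    return nn.Sequential(layers)


class _Identity(nn.Module):
    def forward(self, x, train=False):
        return x

    def backward(self, dy):
        return dy


# ---------------------------------------------------------------------------
# flat-config serialization
# ---------------------------------------------------------------------------

def spec_to_config(spec: ArchitectureSpec) -> dict:
    return {
        "depth": spec.depth,
        "final_width": spec.final_width,
        "input_side": spec.input_side,
        "dropout_rate": spec.dropout_rate,
        "family_code": spec.family_code,
    }


def spec_from_config(cfg: dict) -> ArchitectureSpec:
    code = cfg.get("family_code", "")
    if code.startswith("desk"):
        return build_desk(int(cfg["input_side"]), int(cfg["final_width"]),
                          float(cfg.get("dropout_rate", 0.8)))
    depth = int(cfg["depth"])
    width = int(cfg["final_width"])
    input_side = int(cfg.get("input_side", 360))
    for spec in build_family(input_side):
        if spec.depth == depth and spec.final_width == width:
            return replace(spec, dropout_rate=float(cfg.get("dropout_rate", 0.8)))
    raise ConfigError(f"no family member with depth {depth} and width {width}")
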