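"""ResNet-18 baseline: declarative parameter accounting plus a trainable
instantiation in the ``euslite.nn`` engine.

The baseline of interest has a single-channel grayscale stem and a 2-class
head; only those two pieces differ from the published topology, so the
parameter count is fully determined by the standard layer table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["ResNet18Baseline", "build_resnet18_baseline", "build_resnet18_model"]

# (name, out_channels, stride) for the eight residual blocks
_BLOCKS = [
    ("layer1.0", 64, 1),
    ("layer1.1", 64, 1),
    ("layer2.0", 128, 2),
    ("layer2.1", 128, 1),
    ("layer3.0", 256, 2),
    ("layer3.1", 256, 1),
    ("layer4.0", 512, 2),
    ("layer4.1", 512, 1),
]


@dataclass(frozen=True)
class ResNet18Baseline:
    """Layer-by-layer parameter table of a ResNet-18 variant."""

    in_channels: int
    num_classes: int
    layers: tuple[tuple[str, int], ...]  # (layer name, trainable parameter count)

    @property
    def parameter_count(self) -> int:
        return sum(n for _, n in self.layers)


def _block_params(c_in: int, c_out: int, stride: int, name: str) -> list[tuple[str, int]]:
    rows = [
        (f"{name}.conv1", 9 * c_in * c_out),     # 3x3, no bias
        (f"{name}.bn1", 2 * c_out),
        (f"{name}.conv2", 9 * c_out * c_out),
        (f"{name}.bn2", 2 * c_out),
    ]
    if stride != 1 or c_in != c_out:
        rows += [(f"{name}.downsample.conv", c_in * c_out), (f"{name}.downsample.bn", 2 * c_out)]
    return rows


def build_resnet18_baseline(in_channels: int = 1, num_classes: int = 2) -> ResNet18Baseline:
    """Parameter accounting for ResNet-18 with a configurable stem and head.

    Defaults describe the grayscale 2-class baseline; ``(3, 1000)`` recovers
    the published reference topology.
    """
    rows: list[tuple[str, int]] = [
        ("conv1", 49 * in_channels * 64),  # 7x7 stem, no bias
        ("bn1", 128),
    ]
    c_in = 64
    for name, c_out, stride in _BLOCKS:
        rows += _block_params(c_in, c_out, stride, name)
        c_in = c_out
    rows.append(("fc", 512 * num_classes + num_classes))
    return ResNet18Baseline(in_channels=in_channels, num_classes=num_classes,
                            layers=tuple(rows))


def build_resnet18_model(in_channels: int = 1, num_classes: int = 2,
                         seed: int = 0) -> nn.Sequential:
    """Trainable ResNet-18 (stem conv 7x7/2 pad 3, max-pool 3/2, four stages of
    two basic blocks, global average pool, linear head)."""
    rng = np.random.default_rng(seed)
    stem = nn.Conv2d(in_channels, 64, 7, 2, 3, bias=False, rng=rng, name="conv1")
    stem.needs_input_grad = False
    layers: list[tuple[str, nn.Module]] = [
        ("conv1", stem),
        ("bn1", nn.BatchNorm2d(64, name="bn1")),
        ("relu1", nn.ReLU()),
        ("maxpool", nn.MaxPool2d(3, 2, 1)),
    ]
    c_in = 64
    for name, c_out, stride in _BLOCKS:
        layers.append((name, nn.ResidualBlock(c_in, c_out, stride, rng=rng, name=name)))
        c_in = c_out
    layers.append(("GAP", nn.GlobalAvgPool()))
    layers.append(("fc", nn.Linear(512, num_classes, rng=rng, name="fc")))
    return nn.Sequential(layers)
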