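"""Network containers: a named sequential graph plus the residual block used
by the ResNet-18 baseline.  Layer names double as tap points where forward
activations and backward gradients can be recorded (the hook mechanism behind
Grad-CAM).
"""
from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Dropout, Module, Parameter, ReLU

__all__ = ["Sequential", "ResidualBlock"]


class Sequential(Module):
    """An ordered list of ``(name, module)`` pairs executed in sequence."""

    def __init__(self, layers: list[tuple[str, Module]]):
        self.layers = list(layers)
        self.activations: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._taps: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> Module:
        for n, layer in self.layers:
            if n == name:
                return layer
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for _, layer in self.layers:
            out.extend(layer.parameters())
        return out

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for _, layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng
            elif isinstance(layer, Sequential) or isinstance(layer, ResidualBlock):
                layer.set_dropout_rng(rng)

    def forward(
        self, x: np.ndarray, train: bool = False, taps: tuple[str, ...] = ()
    ) -> np.ndarray:
        self._taps = tuple(taps)
        self.activations = {}
        self.grads = {}
        for name, layer in self.layers:
            x = layer.forward(x, train=train)
            if name in self._taps:
                self.activations[name] = x
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for name, layer in reversed(self.layers):
            if name in self._taps:
                self.grads[name] = dy
            dy = layer.backward(dy)
        return dy

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}:{p.name}"] = p.data
        for j, bn in enumerate(self._batchnorms()):
            state[f"rm{j}"] = bn.running_mean
            state[f"rv{j}"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{i}:{p.name}"], dtype=np.float32)
            p.grad = np.zeros_like(p.data)
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"rm{j}"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"rv{j}"], dtype=np.float32)

    def _batchnorms(self) -> list[BatchNorm2d]:
        out = []
        for _, layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                out.append(layer)
            elif isinstance(layer, (Sequential, ResidualBlock)):
                out.extend(layer._batchnorms())
        return out


class ResidualBlock(Module):
    """conv-bn-relu-conv-bn + identity (or 1x1-conv-bn downsample), then relu."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "block",
    ):
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride, 1, bias=False,
                            rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(out_channels, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, bias=False,
                            rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_channels, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.downsample: tuple[Conv2d, BatchNorm2d] | None = None
        if stride != 1 or in_channels != out_channels:
            self.downsample = (
                Conv2d(in_channels, out_channels, 1, stride, 0, bias=False,
                       rng=rng, name=f"{name}.down"),
                BatchNorm2d(out_channels, name=f"{name}.downbn"),
            )

    def parameters(self) -> list[Parameter]:
        out = (
            self.conv1.parameters()
            + self.bn1.parameters()
            + self.conv2.parameters()
            + self.bn2.parameters()
        )
        if self.downsample:
            out += self.downsample[0].parameters() + self.downsample[1].parameters()
        return out

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        pass  # no dropout inside residual blocks

    def _batchnorms(self) -> list[BatchNorm2d]:
        bns = [self.bn1, self.bn2]
        if self.downsample:
            bns.append(self.downsample[1])
        return bns

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.downsample:
            conv, bn = self.downsample
            shortcut = bn.forward(conv.forward(x, train), train)
        else:
            shortcut = x
        return self.relu2.forward(y + shortcut, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(dy)
        d_main = self.bn2.backward(dy)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        dx = self.conv1.backward(d_main)
        if self.downsample:
            conv, bn = self.downsample
            dx = dx + conv.backward(bn.backward(dy))
        else:
            dx = dx + dy
        return dx
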