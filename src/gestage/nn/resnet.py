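"""Residual regression backbones.

Three families are provided:

* ``tiny`` — a four-stage residual network for desk-scale experiments
  (64–96 px inputs, a few thousand parameters, trains in minutes on a CPU);
* ``resnet18`` / ``resnet50`` — the standard residual architectures
  (BasicBlock [2,2,2,2] and Bottleneck [3,4,6,3]) whose last convolutional
  stages expose K = 512 / 2048 feature channels.

Every backbone separates ``forward_features`` (the last convolutional
activations, from which the attention heatmap is read) from ``head``
(spatial pooling plus a fully connected layer producing one scalar age).
The first convolution is parameterized by the number of input slices, and
externally supplied weights with a 3-channel first convolution can be
adapted to any slice count with :func:`adapt_first_conv`.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Linear, MaxPool2d, Module
from .tensor import Tensor

__all__ = ["Backbone", "build_backbone", "adapt_first_conv"]


class BasicBlock(Module):
    expansion = 1

    def __init__(self, inplanes: int, planes: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(inplanes, planes, 3, stride, 1, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.down = None
        if stride != 1 or inplanes != planes:
            self.down = Conv2d(inplanes, planes, 1, stride, 0, rng=rng)
            self.down_bn = BatchNorm2d(planes)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = x if self.down is None else self.down_bn(self.down(x))
        return (out + shortcut).relu()


class Bottleneck(Module):
    expansion = 4

    def __init__(self, inplanes: int, planes: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        width = planes
        self.conv1 = Conv2d(inplanes, width, 1, 1, 0, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride, 1, rng=rng)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, planes * 4, 1, 1, 0, rng=rng)
        self.bn3 = BatchNorm2d(planes * 4)
        self.down = None
        if stride != 1 or inplanes != planes * 4:
            self.down = Conv2d(inplanes, planes * 4, 1, stride, 0, rng=rng)
            self.down_bn = BatchNorm2d(planes * 4)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = x if self.down is None else self.down_bn(self.down(x))
        return (out + shortcut).relu()


class Backbone(Module):
    """Convolutional trunk + pooled regression head with one scalar output."""

    def __init__(self, family: str, in_channels: int, pool: str = "max",
                 seed: int = 0):
        super().__init__()
        if pool not in ("max", "avg"):
            raise ValueError(f"unknown pool type {pool!r}")
        rng = np.random.default_rng(seed)
        self.family = family
        self.in_channels = in_channels
        self.pool = pool
        if family == "tiny":
            widths = (8, 16, 32)
            self.stem = Conv2d(in_channels, widths[0], 3, 2, 1, rng=rng)
            self.stem_bn = BatchNorm2d(widths[0])
            self.stem_pool = None
            self.blocks = [
                BasicBlock(widths[0], widths[1], 2, rng),
                BasicBlock(widths[1], widths[2], 2, rng),
            ]
            self.feature_channels = widths[2]
        elif family in ("resnet18", "resnet50"):
            block = BasicBlock if family == "resnet18" else Bottleneck
            layers = [2, 2, 2, 2] if family == "resnet18" else [3, 4, 6, 3]
            self.stem = Conv2d(in_channels, 64, 7, 2, 3, rng=rng)
            self.stem_bn = BatchNorm2d(64)
            self.stem_pool = MaxPool2d(3, 2, 1)
            self.blocks = []
            inplanes = 64
            for stage, (planes, n_blocks) in enumerate(
                    zip((64, 128, 256, 512), layers)):
                for b in range(n_blocks):
                    stride = 2 if (b == 0 and stage > 0) else 1
                    self.blocks.append(block(inplanes, planes, stride, rng))
                    inplanes = planes * block.expansion
            self.feature_channels = inplanes
        else:
            raise ValueError(f"unknown backbone family {family!r}")
        for i, blk in enumerate(self.blocks):
            setattr(self, f"block{i}", blk)
        self.fc = Linear(self.feature_channels, 1, rng=rng)

    def forward_features(self, x: Tensor) -> Tensor:
        out = self.stem_bn(self.stem(x)).relu()
        if self.stem_pool is not None:
            out = self.stem_pool(out)
        for blk in self.blocks:
            out = blk(out)
        return out

    def head(self, features: Tensor) -> Tensor:
        pooled = (features.max_over_spatial() if self.pool == "max"
                  else features.mean_over((2, 3)))
        return self.fc(pooled).reshape(-1)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.forward_features(x))


def adapt_first_conv(weight: np.ndarray, in_channels: int) -> np.ndarray:
    """Adapt a first-layer kernel trained on 3-channel inputs to a different
    slice count: average the channel kernels, replicate to the requested
    count, and rescale by 3/in_channels so the response to a uniform input
    is preserved."""
    weight = np.asarray(weight)
    if weight.ndim != 4:
        raise ValueError("expected a (out, in, k, k) convolution kernel")
    if weight.shape[1] == in_channels:
        return weight.copy()
    mean_kernel = weight.mean(axis=1, keepdims=True)
    adapted = np.repeat(mean_kernel, in_channels, axis=1)
    return adapted * (3.0 / in_channels)


def build_backbone(family: str, in_channels: int, pool: str = "max",
                   seed: int = 0, weights: str | dict | None = None) -> Backbone:
    """Construct a backbone, optionally initializing from a saved state dict
    (an .npz path or a mapping). A first convolution stored for 3 channels
    is adapted to the requested channel count."""
    net = Backbone(family, in_channels, pool=pool, seed=seed)
    if weights is not None:
        if isinstance(weights, (str, bytes)):
            with np.load(weights) as archive:
                state = {k: archive[k] for k in archive.files}
        else:
            state = dict(weights)
        first = "stem.weight"
        if first in state and state[first].shape[1] != in_channels:
            state[first] = adapt_first_conv(state[first], in_channels)
        own = dict(net.named_parameters())
        own_buffers = dict(net.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                if name in own_buffers:
                    np.copyto(own_buffers[name], value)
            elif key in own and own[key].data.shape == value.shape:
                own[key].data = value.astype(np.float32).copy()
    return net
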