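"""Neural-network building blocks (convolution, batch norm, linear, pooling).

Convolutions use an im2col lowering onto BLAS matrix products, which is the
fastest pure-NumPy route at the small image sizes this package trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, default_dtype

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "MaxPool2d", "Sequential"]


class Module:
    """Base class: tracks parameters/submodules, train/eval mode, state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy()
                      for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                target = buffers[key[len("buffer:"):]]
                np.copyto(target, value)
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data = value.astype(p.data.dtype).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape).astype(default_dtype()),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = _he_init(rng, (out_channels, in_channels,
                                     kernel_size, kernel_size), fan_in)
        self.bias = (Tensor(np.zeros(out_channels, dtype=default_dtype()),
                            requires_grad=True) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        s, p, k = self.stride, self.padding, self.kernel_size
        xd = x.data
        n, c, h, wid = xd.shape
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (xd.shape[2] - k) // s + 1
        wo = (xd.shape[3] - k) // s + 1
        win = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * ho * wo, c * k * k)
        wmat = w.data.reshape(w.data.shape[0], -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        y = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

        def bw(g):
            gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)
                                      ).reshape(n * ho * wo, -1)
            grads = [(w, (gf.T @ cols).reshape(w.data.shape))]
            if self.bias is not None:
                grads.append((self.bias, gf.sum(axis=0)))
            if x.requires_grad:
                dcols = (gf @ wmat).reshape(n, ho, wo, c, k, k)
                dxp = np.zeros(xd.shape, dtype=xd.dtype)
                for ki in range(k):
                    for kj in range(k):
                        dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                            dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                dx = dxp[:, :, p:p + h, p:p + wid] if p else dxp
                grads.append((x, dx))
            return grads

        parents = (x, w) + ((self.bias,) if self.bias is not None else ())
        return Tensor._node(y, parents, bw)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=default_dtype()),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=default_dtype()),
                           requires_grad=True)
        self._buffers["running_mean"] = np.zeros(num_features, dtype=default_dtype())
        self._buffers["running_var"] = np.ones(num_features, dtype=default_dtype())

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        if self.training:
            mu = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm += self.momentum * (mu - rm)
            rv += self.momentum * (var - rv)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu[:, None, None]) * ivar[:, None, None]
        y = self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]
        training = self.training

        def bw(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            grads = [(self.gamma, dgamma), (self.beta, dbeta)]
            if x.requires_grad:
                gxh = g * self.gamma.data[:, None, None]
                if training:
                    dx = (ivar[:, None, None] / m) * (
                        m * gxh
                        - gxh.sum(axis=(0, 2, 3))[:, None, None]
                        - xhat * (gxh * xhat).sum(axis=(0, 2, 3))[:, None, None])
                else:
                    dx = gxh * ivar[:, None, None]
                grads.append((x, dx))
            return grads

        return Tensor._node(y, (x, self.gamma, self.beta), bw)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features, dtype=default_dtype()),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class MaxPool2d(Module):
    """Windowed max pooling (used only in the standard ResNet stem)."""

    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        xd = x.data
        n, c, h, w = xd.shape
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)),
                        constant_values=-np.inf)
        ho = (xd.shape[2] - k) // s + 1
        wo = (xd.shape[3] - k) // s + 1
        win = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = np.argmax(flat, axis=4)
        y = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]

        def bw(g):
            dxp = np.zeros(xd.shape, dtype=xd.dtype)
            ki, kj = np.unravel_index(idx, (k, k))
            rows = (np.arange(ho)[None, None, :, None] * s + ki)
            colx = (np.arange(wo)[None, None, None, :] * s + kj)
            nn_idx = np.arange(n)[:, None, None, None]
            cc = np.arange(c)[None, :, None, None]
            np.add.at(dxp, (nn_idx, cc, rows, colx), g)
            dx = dxp[:, :, p:p + h, p:p + w] if p else dxp
            return ((x, dx),)

        return Tensor._node(y, (x,), bw)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._seq = list(modules)
        for i, mod in enumerate(modules):
            setattr(self, f"m{i}", mod)

    def forward(self, x: Tensor) -> Tensor:
        for mod in self._seq:
            x = mod(x)
        return x
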