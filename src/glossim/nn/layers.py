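"""Layer primitives built on the autodiff engine: parameter container, dense
and convolutional layers (with optional autoregressive masks), pooling and
upsampling."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["Parameter", "Module", "Dense", "Conv2d", "MaskedConv2d",
           "avg_pool2d", "global_avg_pool", "upsample_nearest",
           "raster_mask"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny parameter registry; subclasses assign Parameters/Modules as attrs."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=np.float32).reshape(p.data.shape)


def _fan_in_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
    return (rng.standard_normal(shape) * scale).astype(np.float32)


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        self.w = Parameter(_fan_in_init(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, rng, cin: int, cout: int, ksize: int, stride: int = 1,
                 padding: int | None = None):
        self.stride = stride
        self.padding = ksize // 2 if padding is None else padding
        fan_in = ksize * ksize * cin
        self.w = Parameter(_fan_in_init(rng, (ksize, ksize, cin, cout), fan_in))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


def raster_mask(ksize: int, include_center: bool) -> np.ndarray:
    """Binary (ksize, ksize, 1, 1) mask keeping strictly-previous raster
    positions (mask 'A' excludes the centre pixel; mask 'B' includes it)."""
    m = np.zeros((ksize, ksize), dtype=np.float32)
    c = ksize // 2
    m[:c, :] = 1.0
    m[c, :c] = 1.0
    if include_center:
        m[c, c] = 1.0
    return m[:, :, None, None]


class MaskedConv2d(Module):
    """Convolution whose receptive field is restricted to previous pixels in
    raster order.  The first autoregressive layer uses `include_center=False`
    so the current pixel never sees itself; later layers may include the
    centre because their centre feature already encodes only previous pixels.
    """

    def __init__(self, rng, cin: int, cout: int, ksize: int, include_center: bool):
        fan_in = max(1, int(raster_mask(ksize, include_center).sum())) * cin
        self.w = Parameter(_fan_in_init(rng, (ksize, ksize, cin, cout), fan_in))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))
        self.mask = raster_mask(ksize, include_center)
        self.padding = ksize // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=1, padding=self.padding,
                      mask=self.mask)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, h, w, c = x.shape
    out = x.reshape(b, h // k, k, w // k, k, c)
    return out.mean(axis=2).mean(axis=3)


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=1).mean(axis=1)


def upsample_nearest(x: Tensor, k: int = 2) -> Tensor:
    b, h, w, c = x.shape
    out = x.reshape(b, h, 1, w, 1, c)
    out = out + Tensor(np.zeros((1, 1, k, 1, k, 1), dtype=np.float32))
    return out.reshape(b, h * k, w * k, c)
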