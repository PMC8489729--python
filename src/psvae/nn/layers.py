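"""Network building blocks: dense and convolutional layers with He/Glorot init."""
from __future__ import annotations

import numpy as np

from .conv import conv2d, conv_transpose2d
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Dense", "Conv2d", "ConvTranspose2d"]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Minimal parameter container."""

    def parameters(self) -> list:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> dict:
        """Flat name -> ndarray mapping for checkpointing."""
        out = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor):
                    out[name] = v.data
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{name}.{i}"] = item.data

        walk(self, "")
        return out

    def astype(self, dtype) -> "Module":
        """Cast every parameter/buffer in place (e.g. float32 for speed)."""

        def walk(obj):
            for v in obj.__dict__.values():
                if isinstance(v, Tensor):
                    v.data = v.data.astype(dtype)
                elif isinstance(v, Module):
                    walk(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            walk(item)
                        elif isinstance(item, Tensor):
                            item.data = item.data.astype(dtype)

        walk(self)
        return self

    def load_state_arrays(self, arrays: dict) -> None:
        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor):
                    v.data = np.array(arrays[name], dtype=v.data.dtype)
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Tensor):
                            item.data = np.array(arrays[f"{name}.{i}"], dtype=item.data.dtype)

        walk(self, "")


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: tuple, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: tuple, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(c_in, c_out, kernel, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b, self.stride, self.padding)
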