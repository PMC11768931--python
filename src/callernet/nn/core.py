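"""Minimal feed-forward network kernel: modules, parameters, serialization.

Every layer implements ``forward``/``backward`` explicitly (reverse-mode,
layer-local caching) plus ``complexity`` for analytic shape/FLOP propagation.
All arithmetic is float32; gradients accumulate until ``zero_grad``.
"""

from __future__ import annotations

import io
from typing import Iterator

import numpy as np


class ShapeError(ValueError):
    """An architecture produced a non-positive intermediate size."""


class UnsupportedLayerError(TypeError):
    """FLOP estimation reached a layer without an analytic cost model."""


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: tracks parameters, sub-modules and persistent buffers."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif name in self._buffers:
            self._buffers[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- compute ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def complexity(self, in_shape: tuple[int, ...]) -> tuple[tuple[int, ...], float]:
        """Return (output shape, FLOPs for one input) without running data."""
        raise UnsupportedLayerError(
            f"{type(self).__name__} has no analytic FLOP model"
        )

    # -- state -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer:" + name] = np.asarray(b).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key.startswith("buffer:"):
                self._assign_buffer(key[len("buffer:"):], value)
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = np.ascontiguousarray(value, dtype=np.float32)
        return None

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod = self
        *path, leaf = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        mod.register_buffer(leaf, value)


class Sequential(Module):
    """Ordered chain of layers; backward runs in reverse order."""

    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self._modules[str(i)] = layer

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i: int) -> Module:
        return self.layers[i]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def complexity(self, in_shape):
        total = 0.0
        for layer in self.layers:
            in_shape, fl = layer.complexity(in_shape)
            total += fl
        return in_shape, total


def save_model(model: Module, path) -> None:
    np.savez(path, **model.state_dict())


def load_model(model: Module, path) -> Module:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def serialized_size_bytes(model: Module) -> int:
    """Size of the float32 single-file checkpoint, measured in memory."""
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    return buf.getbuffer().nbytes
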