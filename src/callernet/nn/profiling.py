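"""Model complexity: trainable-parameter counts and analytic FLOP estimates.

FLOP convention: one multiply-accumulate = 2 FLOPs; batch-norm costs a scale
and a shift per element; pooling costs one op per pooled element; activations
one op per element. Estimates are additive over layers and exactly linear in
batch size.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import Module, UnsupportedLayerError


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars (weights and biases)."""
    return int(sum(p.size for p in model.parameters()))


@dataclass(frozen=True)
class FlopsEstimate:
    per_input: float
    batch: int
    output_shape: tuple[int, ...]

    @property
    def per_batch(self) -> float:
        return self.per_input * self.batch


def estimate_flops(model: Module, input_shape: tuple[int, ...], batch: int = 1) -> FlopsEstimate:
    """Analytic FLOPs for one forward pass on ``input_shape`` (no batch axis).

    Raises :class:`UnsupportedLayerError` for layers without a cost model
    rather than silently undercounting.
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    out_shape, fl = model.complexity(tuple(int(s) for s in input_shape))
    return FlopsEstimate(per_input=float(fl), batch=batch, output_shape=tuple(out_shape))


@dataclass
class NetworkDescription:
    """Architecture summary plus derived complexity profile."""

    name: str
    config: dict[str, Any] = field(default_factory=dict)
    parameter_count: int = 0
    flops_per_input: float = 0.0
    serialized_size_bytes: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "config": self.config,
            "parameter_count": self.parameter_count,
            "flops_per_input": self.flops_per_input,
            "gflops_per_input": self.flops_per_input / 1e9,
            "serialized_size_bytes": self.serialized_size_bytes,
            "serialized_size_mb": self.serialized_size_bytes / 2**20,
        }


def describe(model: Module, name: str, input_shape: tuple[int, ...],
             config: dict[str, Any] | None = None) -> NetworkDescription:
    from .core import serialized_size_bytes

    est = estimate_flops(model, input_shape)
    return NetworkDescription(
        name=name,
        config=dict(config or {}),
        parameter_count=count_parameters(model),
        flops_per_input=est.per_input,
        serialized_size_bytes=serialized_size_bytes(model),
    )


# --- post-training int8 weight quantization --------------------------------

def quantize_tensor(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Symmetric per-tensor int8 quantization; returns (int8 values, scale)."""
    scale = float(np.abs(w).max()) / 127.0
    if scale == 0.0:
        scale = 1.0
    q = np.clip(np.round(w / scale), -127, 127).astype(np.int8)
    return q, scale


def dequantize_tensor(q: np.ndarray, scale: float) -> np.ndarray:
    return (q.astype(np.float32)) * scale


def quantize_int8(model: Module) -> Module:
    """Return a copy of ``model`` whose multi-dimensional weights are snapped
    to an int8 grid (weight-only post-training quantization).

    One-dimensional parameters (biases, batch-norm affine terms) stay float32,
    the standard weight-only scheme. The quantized copy carries the int8
    payload on ``_int8_state`` for compact serialization.
    """
    import copy

    qmodel = copy.deepcopy(model)
    payload: dict[str, tuple[np.ndarray, float]] = {}
    for name, p in qmodel.named_parameters():
        if p.data.ndim >= 2:
            q, scale = quantize_tensor(p.data)
            payload[name] = (q, scale)
            p.data = dequantize_tensor(q, scale)
    object.__setattr__(qmodel, "_int8_state", payload)
    return qmodel


def _int8_state_dict(model: Module) -> dict[str, np.ndarray]:
    payload = getattr(model, "_int8_state", None)
    if payload is None:
        raise ValueError("model was not produced by quantize_int8")
    state: dict[str, np.ndarray] = {}
    for name, (q, scale) in payload.items():
        state["q:" + name] = q
        state["scale:" + name] = np.float32(scale)
    for name, p in model.named_parameters():
        if name not in payload:
            state["f:" + name] = p.data
    for name, b in model.named_buffers():
        state["buffer:" + name] = np.asarray(b)
    return state


def save_quantized(model: Module, path) -> None:
    np.savez(path, **_int8_state_dict(model))


def quantized_size_bytes(model: Module) -> int:
    buf = io.BytesIO()
    np.savez(buf, **_int8_state_dict(model))
    return buf.getbuffer().nbytes


__all__ = [
    "count_parameters", "estimate_flops", "FlopsEstimate", "NetworkDescription",
    "describe", "quantize_int8", "quantize_tensor", "dequantize_tensor",
    "save_quantized", "quantized_size_bytes", "UnsupportedLayerError",
]
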