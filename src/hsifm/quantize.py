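"""FP16 post-training quantization (software emulation) and affine
quantization utilities.

``cast_fp16`` replaces every weight of a trained discriminator by its IEEE-754
binary16 value (round-to-nearest-even, saturating at ±65504) — no calibration
data is needed for the float16 path. ``forward_fp16`` evaluates such a model
with activations rounded to binary16 at each layer boundary while each
layer's accumulation runs at full precision, emulating half-precision tensor
hardware. The affine utilities (scale S, zero point Z over a dynamic range
[rmin, rmax]) implement the general integer-quantization arithmetic at
per-tensor, per-channel or group granularity; they are provided as
standalone ops — integer inference engines are out of scope here.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np

from .gan import DiscriminatorModel, score_spectra

FP16_MAX = 65504.0


def round_fp16(x: np.ndarray) -> np.ndarray:
    """Round values to their binary16 representation (saturating), returned
    as float32."""
    x = np.asarray(x, dtype=np.float32)
    return np.clip(x, -FP16_MAX, FP16_MAX).astype(np.float16).astype(np.float32)


def cast_fp16(model: DiscriminatorModel) -> DiscriminatorModel:
    """Half-precision post-training quantization of all weights.

    Returns a new model tagged fp16 whose weights are stored as binary16
    (two bytes each on disk); parameter and MAC counts are unchanged.
    Casting an already-fp16 model warns and returns it untouched.
    """
    if model.precision == "fp16":
        warnings.warn("model is already fp16; cast_fp16 is a no-op", stacklevel=2)
        return model
    out = copy.deepcopy(model)
    for p in out.net.params():
        p.value = (
            np.clip(p.value.astype(np.float32), -FP16_MAX, FP16_MAX)
            .astype(np.float16)
        )
    out.precision = "fp16"
    return out


def forward_fp16(model: DiscriminatorModel, batch) -> np.ndarray:
    """Foreign-material probabilities under the emulated fp16 contract."""
    if model.precision != "fp16":
        raise ValueError("forward_fp16 requires an fp16 model; use cast_fp16 first")
    return score_spectra(model, batch)


@dataclass
class SizeReport:
    """Weight-storage accounting at fp32 vs fp16 (KB = 1024 bytes)."""

    parameter_count: int
    bytes_fp32: int
    bytes_fp16: int
    kb_fp32: float
    kb_fp16: float
    reduction_percent: float


def model_size(parameter_count: int, bytes_per_param: int = 4) -> SizeReport:
    """Storage for a parameter count at full vs half precision.

    KB values use 1024-byte kilobytes, rounded to one decimal; halving the
    width is an exact 50% reduction for pure weight storage.
    """
    if parameter_count < 0:
        raise ValueError("parameter count must be >= 0")
    bytes_fp32 = parameter_count * bytes_per_param
    bytes_fp16 = bytes_fp32 // 2
    reduction = 100.0 * (1.0 - bytes_fp16 / bytes_fp32) if bytes_fp32 else 0.0
    return SizeReport(
        parameter_count=parameter_count,
        bytes_fp32=bytes_fp32,
        bytes_fp16=bytes_fp16,
        kb_fp32=round(bytes_fp32 / 1024.0, 1),
        kb_fp16=round(bytes_fp16 / 1024.0, 1),
        reduction_percent=reduction,
    )


@dataclass
class QuantParams:
    """Affine quantization parameters q = clip(round(x/S) + Z)."""

    S: np.ndarray  # scale, > 0
    Z: np.ndarray  # integer zero point
    rmin: np.ndarray
    rmax: np.ndarray
    nbits: int
    granularity: str  # per_tensor | per_channel | group
    axis: int = 0
    group_size: int = 0

    @property
    def qmin(self) -> int:
        return 0

    @property
    def qmax(self) -> int:
        return 2**self.nbits - 1


def affine_quant_params(
    rmin,
    rmax,
    nbits: int = 8,
    granularity: str = "per_tensor",
    axis: int = 0,
    group_size: int = 0,
) -> QuantParams:
    """Scale and zero point for an unsigned ``nbits`` grid over [rmin, rmax].

    S = (rmax − rmin)/(2^nbits − 1); Z = round(−rmin/S) clipped to the grid.
    For per-channel / group granularity, rmin and rmax are vectors (one
    entry per channel or group along ``axis``). The S/2 reconstruction
    bound holds whenever the range spans zero (so Z is on-grid); a range
    strictly away from zero saturates through the clipped zero point.
    """
    if granularity not in ("per_tensor", "per_channel", "group"):
        raise ValueError(f"unknown granularity {granularity!r}")
    rmin = np.asarray(rmin, dtype=np.float64)
    rmax = np.asarray(rmax, dtype=np.float64)
    if np.any(rmax <= rmin):
        raise ValueError("rmax must exceed rmin for every granularity unit")
    levels = 2**nbits - 1
    S = (rmax - rmin) / levels
    Z = np.clip(np.round(-rmin / S), 0, levels).astype(np.int64)
    return QuantParams(
        S=S, Z=Z, rmin=rmin, rmax=rmax, nbits=nbits,
        granularity=granularity, axis=axis, group_size=group_size,
    )


def _broadcast_shape(qp: QuantParams, tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if qp.granularity == "per_tensor":
        return qp.S, qp.Z
    shape = [1] * tensor.ndim
    if qp.granularity == "per_channel":
        shape[qp.axis] = tensor.shape[qp.axis]
        return qp.S.reshape(shape), qp.Z.reshape(shape)
    # group: channels along axis split into contiguous groups of group_size
    n = tensor.shape[qp.axis]
    if qp.group_size < 1 or n % qp.group_size:
        raise ValueError("axis length must be a multiple of group_size")
    reps = np.repeat(np.arange(n // qp.group_size), qp.group_size)
    shape[qp.axis] = n
    return qp.S[reps].reshape(shape), qp.Z[reps].reshape(shape)


def affine_quantize(tensor: np.ndarray, qp: QuantParams) -> np.ndarray:
    """Map real values onto the integer grid: clip(round(x/S) + Z)."""
    x = np.asarray(tensor, dtype=np.float64)
    S, Z = _broadcast_shape(qp, x)
    return np.clip(np.round(x / S) + Z, qp.qmin, qp.qmax).astype(np.int64)


def affine_dequantize(q: np.ndarray, qp: QuantParams) -> np.ndarray:
    """Reconstruct real values: (q − Z) · S; error ≤ S/2 for in-range x."""
    S, Z = _broadcast_shape(qp, np.asarray(q))
    return (np.asarray(q, dtype=np.float64) - Z) * S
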