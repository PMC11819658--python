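"""Reflectance calibration, cube<->batch reshaping, dummy-band padding, and
batch-size arithmetic.

The inference engines consume pixels as rows of an N×B matrix in row-major
scan order; a cube is flattened so pixel (r, c) becomes row r*W + c. Cameras
deliver 95 real bands over 1000–1700 nm; a 96th dummy band (replicating the
last real band) pads spectra to the model's fixed input length. Batch sizes
are specified either in pixels or in bytes — byte counts convert at
96 bands × 4 bytes per float32 value, nearest integer, with the decimal
meaning of KB/MB/GB (10^3..10^9 bytes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class SpectrumBatch:
    """N×B matrix of pixel spectra, row-major over the source cube."""

    matrix: np.ndarray
    origin: tuple[int, int] | None = None  # (H, W) of the source cube

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("batch must be 2-D (pixels x bands)")

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bands(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BatchPlan:
    """Static (fixed pixel count) or dynamic (min/opt/max range) batching."""

    mode: str  # "static" | "dynamic"
    batch_pixels: int = 0  # static mode
    min_pixels: int = 1  # dynamic mode
    opt_pixels: int = 1
    max_pixels: int = 1

    def validate(self) -> None:
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"unknown batch mode {self.mode!r}")
        if self.mode == "static":
            if self.batch_pixels < 1:
                raise ValueError("static batch_pixels must be >= 1")
        else:
            if not (1 <= self.min_pixels <= self.opt_pixels <= self.max_pixels):
                raise ValueError("dynamic plan requires 1 <= min <= opt <= max")


def calibrate(raw: np.ndarray, white: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Two-point reflectance calibration: (raw - dark) / (white - dark).

    Clipped to [0, 1.5]; the headroom above 1 tolerates specular pixels
    brighter than the white reference.
    """
    raw = np.asarray(raw, dtype=np.float64)
    white = np.asarray(white, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    if not (raw.shape == white.shape == dark.shape):
        raise ValueError("raw, white and dark must share a shape")
    denom = white - dark
    if np.any(denom <= 0):
        raise ZeroDivisionError("white reference must exceed dark everywhere")
    return np.clip((raw - dark) / denom, 0.0, 1.5)


def cube_to_batch(cube) -> SpectrumBatch:
    """Flatten an H×W×B cube to an (H·W)×B batch, row-major."""
    data = np.asarray(getattr(cube, "data", cube))
    if data.ndim != 3:
        raise ValueError("expected an H x W x B cube")
    H, W, B = data.shape
    return SpectrumBatch(matrix=data.reshape(H * W, B), origin=(H, W))


def batch_to_cube(batch, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`cube_to_batch` for a given (H, W); works on N-vectors
    (per-pixel scalars) too, returning an H×W array."""
    arr = np.asarray(getattr(batch, "matrix", batch))
    H, W = shape
    if arr.shape[0] != H * W:
        raise ValueError(f"{arr.shape[0]} rows cannot reshape to {H}x{W}")
    if arr.ndim == 1:
        return arr.reshape(H, W)
    return arr.reshape(H, W, arr.shape[1])


def append_dummy_band(batch: SpectrumBatch) -> SpectrumBatch:
    """Pad 95-band spectra to the model's 96-band input.

    The dummy band replicates the last real band (no reflectance
    discontinuity). Refuses any other width so a padded batch can never be
    padded twice.
    """
    if batch.n_bands != 95:
        raise ValueError(
            f"dummy band applies to 95-band batches only, got {batch.n_bands}"
        )
    m = batch.matrix
    return SpectrumBatch(
        matrix=np.concatenate([m, m[:, -1:]], axis=1), origin=batch.origin
    )


def bytes_to_pixels(n_bytes: int, bands: int = 96) -> int:
    """Pixels per batch for a byte budget: nearest integer of
    n_bytes / (bands × 4), minimum 1 (float32 spectra)."""
    if n_bytes <= 0 or bands <= 0:
        raise ValueError("n_bytes and bands must be positive")
    return max(1, int(math.floor(n_bytes / (bands * 4) + 0.5)))


def byte_ladder(bands: int = 96) -> dict[int, int]:
    """The 1 KB..1 GB (decimal powers of ten) batch ladder in pixels."""
    return {10**e: bytes_to_pixels(10**e, bands) for e in range(3, 10)}


def partition(batch: SpectrumBatch, plan: BatchPlan) -> list[SpectrumBatch]:
    """Split a batch per plan; concatenating the pieces restores the input.

    Static: fixed-size chunks, the last possibly short. Dynamic: a single
    pass is allowed for any size up to max; larger inputs are rejected,
    mirroring an engine built with a fixed upper bound.
    """
    plan.validate()
    m = batch.matrix
    if plan.mode == "static":
        size = plan.batch_pixels
        return [
            SpectrumBatch(matrix=m[i : i + size], origin=batch.origin)
            for i in range(0, m.shape[0], size)
        ]
    if m.shape[0] > plan.max_pixels:
        raise ValueError(
            f"batch of {m.shape[0]} pixels exceeds dynamic max {plan.max_pixels}"
        )
    return [SpectrumBatch(matrix=m, origin=batch.origin)]
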