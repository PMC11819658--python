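"""Line-scan camera throughput simulation and the latency protocol.

Two hypothetical push-broom cameras (modelled on commercial SWIR and NIR
units, both delivering 96 bands after the dummy band) define the hypercube
geometry: 320×800 px (256,000 spectra) and 640×168 px (107,520 spectra).
Latency follows the warm-up protocol — five untimed preliminary runs, then
ten timed repetitions — with an injectable clock so the contract itself is
testable. Throughput converts to a hypercube rate (cubes/s) which is judged
against poultry-line speed: each bird yields two halved fillets, so 140 BPM
demands 4.7 fillets/s and 250 BPM demands 8.3.

None of the paper-grade wall-clock numbers are reproducible off the original
hardware; this module reproduces the measurement protocol and the unit
arithmetic, not the timings.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field


@dataclass
class CameraSpec:
    """A hypothetical line-scan camera and its configured hypercube dims."""

    name: str
    spatial_pixels: int  # detector width
    native_bands: int
    wavelength_range_nm: tuple[float, float]
    max_line_rate: float  # lines/s
    res_cross_mm: float
    res_along_mm: float
    image_width_px: int
    image_lines: int
    bands: int = 96  # delivered to the model, incl. dummy band

    def __post_init__(self) -> None:
        if self.image_width_px > self.spatial_pixels:
            raise ValueError("configured width exceeds detector width")
        for v in (
            self.spatial_pixels, self.native_bands, self.max_line_rate,
            self.res_cross_mm, self.res_along_mm, self.image_width_px,
            self.image_lines, self.bands,
        ):
            if v <= 0:
                raise ValueError("camera parameters must be positive")


def swir_camera() -> CameraSpec:
    """256k-pixel SWIR preset: 320×800 px at 0.4/0.3 mm, 45 lines/s."""
    return CameraSpec(
        name="swir_320x800",
        spatial_pixels=320,
        native_bands=256,
        wavelength_range_nm=(1000.0, 2500.0),
        max_line_rate=45.0,
        res_cross_mm=0.4,
        res_along_mm=0.3,
        image_width_px=320,
        image_lines=800,
    )


def nir_camera() -> CameraSpec:
    """108k-pixel NIR preset: 640×168 px at 0.4/0.8 mm, 670 lines/s."""
    return CameraSpec(
        name="nir_640x168",
        spatial_pixels=640,
        native_bands=224,
        wavelength_range_nm=(900.0, 1700.0),
        max_line_rate=670.0,
        res_cross_mm=0.4,
        res_along_mm=0.8,
        image_width_px=640,
        image_lines=168,
    )


CAMERA_PRESETS = {"swir_320x800": swir_camera, "nir_640x168": nir_camera}


@dataclass
class LatencyStats:
    mean_s: float
    sd_s: float
    warmup_runs: int
    reps: int
    times_s: list[float] = field(default_factory=list)


def measure_latency(
    engine, batch, warmup: int = 5, reps: int = 10, clock=time.perf_counter
) -> LatencyStats:
    """Warm-up-then-measure latency protocol.

    ``engine`` is executed ``warmup`` times untimed, then ``reps`` times with
    a timestamp before and after each call; the mean and (population)
    standard deviation cover the timed runs only. Data loading, engine
    construction and preprocessing happen outside and are never timed.
    ``clock`` is injectable for deterministic tests.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if warmup < 0:
        raise ValueError("warmup must be >= 0")
    for i in range(warmup):
        try:
            engine(batch)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"engine failed during warm-up run {i}") from exc
    times: list[float] = []
    for i in range(reps):
        t0 = clock()
        try:
            engine(batch)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"engine failed during timed run {i}") from exc
        times.append(clock() - t0)
    mean = sum(times) / reps
    sd = math.sqrt(sum((t - mean) ** 2 for t in times) / reps) if reps > 1 else 0.0
    return LatencyStats(mean_s=mean, sd_s=sd, warmup_runs=warmup, reps=reps, times_s=times)


def throughput(total_bytes: float, total_seconds: float) -> float:
    """Inferred data per second in MB/s (MB = 10^6 bytes)."""
    if total_bytes < 0:
        raise ValueError("total_bytes must be >= 0")
    if total_seconds <= 0:
        raise ValueError("total_seconds must be positive")
    return (total_bytes / total_seconds) / 1e6


def hypercube_pixels(camera: CameraSpec) -> int:
    """Spectra per hypercube: configured width × lines."""
    return camera.image_width_px * camera.image_lines


def hypercube_rate(pixels_per_s: float, camera: CameraSpec) -> tuple[float, int]:
    """Hypercubes processed per second: exact value and whole-cube floor."""
    if pixels_per_s <= 0:
        raise ValueError("pixel rate must be positive")
    exact = pixels_per_s / hypercube_pixels(camera)
    return exact, int(math.floor(exact))


def required_fillet_rate(bpm: float) -> float:
    """Halved fillets per second at a given birds-per-minute line speed
    (two fillets per bird), reported to one decimal."""
    if bpm < 0:
        raise ValueError("bpm must be >= 0")
    return round(bpm * 2.0 / 60.0, 1)


@dataclass
class FeasibilityVerdict:
    feasible: bool
    cubes_per_s: float
    required_per_s: float
    margin: float  # cubes/s above (or below, negative) the requirement


def feasibility(cubes_per_s: float, bpm: float) -> FeasibilityVerdict:
    """Can the inference rate keep up with the line? Boundary inclusive."""
    if cubes_per_s < 0 or bpm < 0:
        raise ValueError("inputs must be >= 0")
    req = required_fillet_rate(bpm)
    return FeasibilityVerdict(
        feasible=cubes_per_s >= req,
        cubes_per_s=cubes_per_s,
        required_per_s=req,
        margin=cubes_per_s - req,
    )


@dataclass
class ScanGeometry:
    required_width_px: int
    required_lines: int
    fits: bool


def scan_geometry(
    fillet_len_mm: float,
    fillet_wid_mm: float,
    camera: CameraSpec,
    orientation: str = "perpendicular",
) -> ScanGeometry:
    """Pixels and scan lines needed to cover a fillet, and whether the
    configured hypercube dimensions suffice.

    ``perpendicular``: fillet length runs along the transport direction
    (width across the scan line); ``parallel``: length lies along the scan
    line.
    """
    if fillet_len_mm <= 0 or fillet_wid_mm <= 0:
        raise ValueError("fillet dimensions must be positive")
    if orientation == "perpendicular":
        cross, along = fillet_wid_mm, fillet_len_mm
    elif orientation == "parallel":
        cross, along = fillet_len_mm, fillet_wid_mm
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    req_px = math.ceil(cross / camera.res_cross_mm)
    req_lines = math.ceil(along / camera.res_along_mm)
    return ScanGeometry(
        required_width_px=req_px,
        required_lines=req_lines,
        fits=(req_px <= camera.image_width_px and req_lines <= camera.image_lines),
    )


def acquisition_limit(camera: CameraSpec) -> float:
    """Cubes/s the optics alone allow: max line rate / lines per cube.

    Reported alongside the inference-based hypercube rate, never folded into
    it.
    """
    return camera.max_line_rate / camera.image_lines
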