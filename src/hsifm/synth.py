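"""Synthetic hyperspectral fillet scenes with ground-truth contamination masks.

Real inspection data — NIR hypercubes of broiler breast fillets on a blue
conveyor belt, clean or carrying small foreign-material (FM) patches — is not
publicly deposited, so this module fabricates statistically analogous scenes:
an elliptical fillet of muscle spectra with fat/connective ("non-muscle")
blobs along its margin, square FM patches of a few millimetres stamped inside
the fillet, per-pixel i.i.d. Gaussian spectral noise, and an integer label
map (0 belt, 1 muscle, 2 non-muscle, 3 FM) aligned to the cube.

Endmember spectra are smooth low-frequency curves in [0, 1]; the classes are
built to be pairwise distinguishable (positive spectral angles, configurable
muscle/non-muscle mean separation) so that downstream tissue clustering and
anomaly scoring have the structure they rely on in real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Hypercube

LABEL_BELT = 0
LABEL_MUSCLE = 1
LABEL_NONMUSCLE = 2
LABEL_FM = 3


@dataclass
class EndmemberLibrary:
    """Per-class reference reflectance spectra.

    class_names holds ``muscle``, ``nonmuscle``, ``belt`` and ``fm_1..fm_K``;
    ``spectra`` maps each name to a length-B reflectance vector in [0, 1];
    ``wavelengths`` spans 1000–1700 nm.
    """

    class_names: list[str]
    spectra: dict[str, np.ndarray]
    wavelengths: np.ndarray

    @property
    def band_count(self) -> int:
        return len(self.wavelengths)

    def fm_names(self) -> list[str]:
        return [n for n in self.class_names if n.startswith("fm_")]


@dataclass
class SceneSpec:
    """Geometry, contamination and noise parameters of one synthetic scene."""

    height_px: int = 64
    width_px: int = 64
    res_cross_mm: float = 0.4
    res_along_mm: float = 0.4
    fm_sizes_mm: tuple[float, ...] = (2.0, 5.0)
    n_fm: int = 4
    nonmuscle_fraction: float = 0.12
    noise_sd: float = 0.01
    seed: int = 0
    margin_px: int = 3

    def validate(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("scene dimensions must be positive")
        if self.res_cross_mm <= 0 or self.res_along_mm <= 0:
            raise ValueError("pixel resolutions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_fm < 0:
            raise ValueError("n_fm must be >= 0")
        if self.n_fm > 0 and not self.fm_sizes_mm:
            raise ValueError("fm_sizes_mm empty with n_fm > 0")


@dataclass
class LabelMap:
    """H×W integer ground truth: 0 belt, 1 muscle, 2 non-muscle, 3 FM."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf (12.5 -> 13)."""
    return int(math.floor(x + 0.5))


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in radians between two spectra (0 iff proportional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cos = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _smooth_bumps(
    wl: np.ndarray,
    baseline: float,
    bumps: list[tuple[float, float, float]],
    slope: float = 0.0,
) -> np.ndarray:
    """Smooth spectrum: baseline + linear slope + Gaussian bumps (center, width, amp)."""
    x = (wl - wl[0]) / (wl[-1] - wl[0])  # 0..1
    y = baseline + slope * x
    for center, width, amp in bumps:
        y = y + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return np.clip(y, 0.0, 1.0)


def make_endmembers(
    band_count: int = 96,
    seed: int = 0,
    n_fm_classes: int = 4,
    min_separation: float = 0.15,
) -> EndmemberLibrary:
    """Build a seeded endmember library over 1000–1700 nm.

    Class shapes are fixed (muscle: mid reflectance with water-absorption
    dips; non-muscle fat: brighter with C–H features; belt: dark and flat;
    four FM families: polymer/metal/wood/rubber-like); a small seeded smooth
    perturbation individualises each library. ``min_separation`` is the
    guaranteed gap between muscle and non-muscle mean reflectance, which is
    what the 1-D tissue GMM clusters on.
    """
    if band_count < 2:
        raise ValueError("band_count must be >= 2")
    rng = np.random.default_rng(seed)
    wl = np.linspace(1000.0, 1700.0, band_count)

    base: dict[str, np.ndarray] = {}
    base["muscle"] = _smooth_bumps(
        wl, 0.42, [(1200, 60, -0.10), (1450, 55, -0.18)], slope=-0.05
    )
    base["nonmuscle"] = _smooth_bumps(
        wl, 0.62, [(1210, 45, 0.08), (1390, 50, -0.06), (1720, 80, 0.05)], slope=0.02
    )
    base["belt"] = _smooth_bumps(wl, 0.18, [(1100, 120, 0.04)], slope=-0.03)
    fm_shapes = [
        _smooth_bumps(wl, 0.75, [(1180, 40, 0.10), (1420, 60, 0.08)], slope=-0.10),
        _smooth_bumps(wl, 0.30, [], slope=0.25),
        _smooth_bumps(wl, 0.55, [(1200, 70, -0.15), (1480, 90, 0.12)], slope=-0.12),
        _smooth_bumps(wl, 0.10, [(1300, 90, 0.06)], slope=0.04),
    ]
    names = ["muscle", "nonmuscle", "belt"]
    for i in range(n_fm_classes):
        name = f"fm_{i + 1}"
        names.append(name)
        shape = fm_shapes[i % len(fm_shapes)].copy()
        if i >= len(fm_shapes):  # extra classes get a deterministic shift
            shape = np.clip(shape + 0.07 * ((i // len(fm_shapes)) % 3 - 1), 0, 1)
        base[name] = shape

    spectra: dict[str, np.ndarray] = {}
    for name in names:
        # low-frequency seeded perturbation keeps spectra smooth & in range
        knots = rng.normal(0.0, 0.015, size=6)
        pert = np.interp(np.linspace(0, 5, band_count), np.arange(6), knots)
        spectra[name] = np.clip(base[name] + pert, 0.0, 1.0)

    gap = float(spectra["nonmuscle"].mean() - spectra["muscle"].mean())
    if gap < min_separation:
        spectra["nonmuscle"] = np.clip(
            spectra["nonmuscle"] + (min_separation - gap), 0.0, 1.0
        )
    return EndmemberLibrary(class_names=names, spectra=spectra, wavelengths=wl)


def _fillet_ellipse(scene: SceneSpec) -> tuple[float, float, float, float]:
    """Center (cy, cx) and semi-axes (ay, ax) of the inscribed fillet ellipse."""
    cy = (scene.height_px - 1) / 2.0
    cx = (scene.width_px - 1) / 2.0
    ay = scene.height_px / 2.0 - scene.margin_px
    ax = scene.width_px / 2.0 - scene.margin_px
    if ay <= 1 or ax <= 1:
        raise ValueError("scene too small for fillet after margin")
    return cy, cx, ay, ax


def _inside_ellipse(rr: np.ndarray, cc: np.ndarray, scene: SceneSpec) -> np.ndarray:
    cy, cx, ay, ax = _fillet_ellipse(scene)
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def fm_patch_side_px(size_mm: float, res_mm: float) -> int:
    """Rasterised FM square side: round-half-up of size_mm / res_mm, minimum 1."""
    return max(1, round_half_up(size_mm / res_mm))


def synth_cube(
    scene: SceneSpec, lib: EndmemberLibrary
) -> tuple[Hypercube, LabelMap]:
    """Render one scene: label geometry first, then spectra + noise.

    Raises a placement error when an FM patch cannot be placed fully inside
    the fillet ellipse.
    """
    scene.validate()
    rng = np.random.default_rng(scene.seed)
    H, W, B = scene.height_px, scene.width_px, lib.band_count

    rr, cc = np.mgrid[0:H, 0:W]
    labels = np.where(_inside_ellipse(rr, cc, scene), LABEL_MUSCLE, LABEL_BELT)
    labels = labels.astype(np.int64)

    # non-muscle blobs seeded on the fillet rim, grown by a few dilations
    fillet = labels == LABEL_MUSCLE
    n_fillet = int(fillet.sum())
    target = int(scene.nonmuscle_fraction * n_fillet)
    if target > 0:
        cy, cx, ay, ax = _fillet_ellipse(scene)
        rim = fillet & (
            ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 >= 0.55
        )
        rim_idx = np.flatnonzero(rim)
        n_seeds = max(1, target // 60)
        seeds = rng.choice(rim_idx, size=min(n_seeds, rim_idx.size), replace=False)
        blob = np.zeros((H, W), dtype=bool)
        blob.flat[seeds] = True
        grown = blob
        while int((grown & fillet).sum()) < target:
            g = grown.copy()
            g[1:, :] |= grown[:-1, :]
            g[:-1, :] |= grown[1:, :]
            g[:, 1:] |= grown[:, :-1]
            g[:, :-1] |= grown[:, 1:]
            if g.sum() == grown.sum():
                break
            grown = g
        labels[grown & fillet] = LABEL_NONMUSCLE

    # FM squares fully inside the ellipse
    fm_assignments: list[tuple[int, int, int, str]] = []
    fm_names = lib.fm_names()
    if scene.n_fm > 0 and not fm_names:
        raise ValueError("library has no FM classes")
    for i in range(scene.n_fm):
        size_mm = scene.fm_sizes_mm[i % len(scene.fm_sizes_mm)]
        side = fm_patch_side_px(size_mm, scene.res_cross_mm)
        placed = False
        for _ in range(200):
            r0 = int(rng.integers(0, max(1, H - side)))
            c0 = int(rng.integers(0, max(1, W - side)))
            corners_r = np.array([r0, r0, r0 + side - 1, r0 + side - 1])
            corners_c = np.array([c0, c0 + side - 1, c0, c0 + side - 1])
            if not _inside_ellipse(corners_r, corners_c, scene).all():
                continue
            block = labels[r0 : r0 + side, c0 : c0 + side]
            if (block == LABEL_FM).any():
                continue
            name = fm_names[int(rng.integers(0, len(fm_names)))]
            labels[r0 : r0 + side, c0 : c0 + side] = LABEL_FM
            fm_assignments.append((r0, c0, side, name))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place a {side}x{side} px FM patch inside the fillet"
            )

    # spectra: class endmember + iid Gaussian noise, clipped to [0, 1]
    data = np.empty((H, W, B), dtype=np.float64)
    class_of_label = {
        LABEL_BELT: "belt",
        LABEL_MUSCLE: "muscle",
        LABEL_NONMUSCLE: "nonmuscle",
    }
    for lab, name in class_of_label.items():
        data[labels == lab] = lib.spectra[name]
    for r0, c0, side, name in fm_assignments:
        data[r0 : r0 + side, c0 : c0 + side] = lib.spectra[name]
    if scene.noise_sd > 0:
        data = data + rng.normal(0.0, scene.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0)

    cube = Hypercube(
        data=data.astype(np.float32),
        wavelengths=lib.wavelengths.copy(),
        res_cross_mm=scene.res_cross_mm,
        res_along_mm=scene.res_along_mm,
        provenance=f"synthetic scene seed={scene.seed}",
    )
    return cube, LabelMap(labels=labels)


def synth_dataset(
    n_clean: int,
    n_contaminated: int,
    scene: SceneSpec,
    lib: EndmemberLibrary,
    seed: int = 0,
) -> list[tuple[Hypercube, LabelMap]]:
    """Seeded inventory of clean-then-contaminated scenes.

    Clean scenes carry no FM labels; per-scene seeds are derived from
    ``seed`` so the whole dataset is reproducible.
    """
    if n_clean < 0 or n_contaminated < 0:
        raise ValueError("counts must be >= 0")
    out: list[tuple[Hypercube, LabelMap]] = []
    rng = np.random.default_rng(seed)
    for i in range(n_clean + n_contaminated):
        sub = int(rng.integers(0, 2**31 - 1))
        spec_i = SceneSpec(
            height_px=scene.height_px,
            width_px=scene.width_px,
            res_cross_mm=scene.res_cross_mm,
            res_along_mm=scene.res_along_mm,
            fm_sizes_mm=scene.fm_sizes_mm,
            n_fm=0 if i < n_clean else scene.n_fm,
            nonmuscle_fraction=scene.nonmuscle_fraction,
            noise_sd=scene.noise_sd,
            seed=sub,
            margin_px=scene.margin_px,
        )
        out.append(synth_cube(spec_i, lib))
    return out
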