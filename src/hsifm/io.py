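"""Artifact I/O: hypercubes (ENVI and .npz), label masks (PNG and .npz),
model containers (HDF5), and YAML configuration.

Cubes are stored as a plain-text ENVI header (.hdr) beside a raw binary
payload, band-interleaved-by-line by default; BSQ and BIP interleaves read
back to the identical in-memory array. Masks are 8-bit PNG label images with
an .npz mirror. Trained discriminators persist to a single HDF5 file keyed
by layer name; weights round-trip bitwise at their stored precision (an fp16
model stores two bytes per weight on disk).

All writers are deterministic for identical inputs — payloads contain no
timestamps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np
import yaml
from PIL import Image


class FormatError(ValueError):
    """Malformed or internally inconsistent file content."""


class UnsupportedFormatError(FormatError):
    """Recognisably foreign dialect or extension."""


@dataclass
class Hypercube:
    """H×W×B reflectance cube with wavelength and pixel-resolution metadata."""

    data: np.ndarray  # (H, W, B) float reflectance
    wavelengths: np.ndarray  # (B,) nm, strictly increasing
    res_cross_mm: float = 0.4
    res_along_mm: float = 0.4
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != self.wavelengths.shape[0]:
            raise ValueError("band count does not match wavelengths")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}
_INTERLEAVES = ("bil", "bsq", "bip")


def write_cube(cube: Hypercube, path: str, interleave: str = "bil") -> None:
    """Write an ENVI .hdr + raw pair, or a compressed .npz when path ends in .npz."""
    if path.endswith(".npz"):
        np.savez_compressed(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            res_cross_mm=cube.res_cross_mm,
            res_along_mm=cube.res_along_mm,
            provenance=np.array(cube.provenance),
        )
        return
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise UnsupportedFormatError(f"unknown interleave {interleave!r}")
    data = np.ascontiguousarray(cube.data, dtype=np.float32)
    H, W, B = data.shape
    if interleave == "bip":
        payload = data  # (lines, samples, bands)
    elif interleave == "bil":
        payload = np.transpose(data, (0, 2, 1))  # (lines, bands, samples)
    else:  # bsq
        payload = np.transpose(data, (2, 0, 1))  # (bands, lines, samples)
    raw_path = _raw_path(path)
    hdr_lines = [
        "ENVI",
        "description = {" + (cube.provenance or "hsifm cube") + "}",
        f"samples = {W}",
        f"lines = {H}",
        f"bands = {B}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(f"{w:.4f}" for w in cube.wavelengths) + "}",
        f"pixel resolution cross mm = {cube.res_cross_mm}",
        f"pixel resolution along mm = {cube.res_along_mm}",
    ]
    with open(_hdr_path(path), "w") as fh:
        fh.write("\n".join(hdr_lines) + "\n")
    np.ascontiguousarray(payload).tofile(raw_path)


def _hdr_path(path: str) -> str:
    return path if path.endswith(".hdr") else path + ".hdr"


def _raw_path(path: str) -> str:
    return path[:-4] if path.endswith(".hdr") else path


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise UnsupportedFormatError("not an ENVI header")
    fields: dict[str, str] = {}
    key, buf, in_brace = None, [], False
    for line in text.splitlines()[1:]:
        if in_brace:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)  # type: ignore[index]
                in_brace = False
            continue
        if "=" not in line:
            continue
        k, v = line.split("=", 1)
        k, v = k.strip().lower(), v.strip()
        if v.startswith("{") and "}" not in v:
            key, buf, in_brace = k, [v], True
        else:
            fields[k] = v
    return fields


def read_cube(path: str) -> Hypercube:
    """Read a cube written by :func:`write_cube` (ENVI pair or .npz)."""
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            return Hypercube(
                data=z["data"],
                wavelengths=z["wavelengths"],
                res_cross_mm=float(z["res_cross_mm"]),
                res_along_mm=float(z["res_along_mm"]),
                provenance=str(z["provenance"]),
            )
    hdr_path = _hdr_path(path)
    if not os.path.exists(hdr_path):
        raise FileNotFoundError(hdr_path)
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    try:
        W = int(fields["samples"])
        H = int(fields["lines"])
        B = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
        interleave = fields.get("interleave", "bil").lower()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad ENVI header: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise UnsupportedFormatError(f"unknown interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise UnsupportedFormatError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    raw = np.fromfile(_raw_path(path), dtype=dtype)
    if raw.size != H * W * B:
        raise FormatError(
            f"payload holds {raw.size} values but header declares {H}x{W}x{B}"
        )
    if interleave == "bip":
        data = raw.reshape(H, W, B)
    elif interleave == "bil":
        data = np.transpose(raw.reshape(H, B, W), (0, 2, 1))
    else:  # bsq
        data = np.transpose(raw.reshape(B, H, W), (1, 2, 0))
    wl_text = fields.get("wavelength", "")
    wl_text = wl_text.strip().strip("{}").strip()
    if wl_text:
        wavelengths = np.array([float(t) for t in wl_text.split(",")])
    else:
        wavelengths = np.arange(B, dtype=float)
    if wavelengths.size != B:
        raise FormatError("wavelength list length does not match band count")
    return Hypercube(
        data=np.ascontiguousarray(data),
        wavelengths=wavelengths,
        res_cross_mm=float(fields.get("pixel resolution cross mm", 0.4)),
        res_along_mm=float(fields.get("pixel resolution along mm", 0.4)),
        provenance=fields.get("description", "").strip("{} "),
    )


def write_mask(mask, path: str) -> None:
    """Write an integer label map as 8-bit PNG or .npz (lossless)."""
    labels = np.asarray(getattr(mask, "labels", mask))
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("label map must be integer")
    if path.endswith(".npz"):
        np.savez_compressed(path, labels=labels)
        return
    if labels.min() < 0 or labels.max() > 255:
        raise FormatError("PNG masks support labels 0..255")
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path)


def read_mask(path: str) -> np.ndarray:
    """Read a label map written by :func:`write_mask`."""
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            labels = z["labels"]
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError("label map payload must be integer")
        return labels
    img = Image.open(path)
    if img.mode not in ("L", "P", "I", "I;16"):
        raise FormatError(f"mask PNG must be single-channel, got mode {img.mode}")
    return np.asarray(img, dtype=np.int64)


def save_model(model, path: str) -> None:
    """Persist a discriminator to HDF5, bitwise at its stored precision."""
    state = model.state_dict()
    with h5py.File(path, "w") as f:
        f.attrs["precision"] = state["precision"]
        f.attrs["channel_id"] = state["channel_id"]
        f.attrs["seed"] = state["seed"]
        f.attrs["epochs"] = state["epochs"]
        f.attrs["format"] = "hsifm-discriminator-v1"
        arch = f.create_group("arch")
        for k, v in state["arch"].items():
            arch.attrs[k] = v
        layers = f.create_group("layers")
        for name, arrays in state["layers"].items():
            g = layers.create_group(name)
            for pname, arr in arrays.items():
                g.create_dataset(pname, data=arr)


def load_model(path: str):
    """Load a discriminator saved by :func:`save_model`."""
    from .gan import DiscriminatorModel  # circular at import time otherwise

    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "hsifm-discriminator-v1":
            raise UnsupportedFormatError("not an hsifm discriminator file")
        precision = str(f.attrs["precision"])
        expected_width = 2 if precision == "fp16" else 4
        state = {
            "precision": precision,
            "channel_id": str(f.attrs["channel_id"]),
            "seed": int(f.attrs["seed"]),
            "epochs": int(f.attrs["epochs"]),
            "arch": {k: f["arch"].attrs[k] for k in f["arch"].attrs},
            "layers": {},
        }
        for name in f["layers"]:
            g = f["layers"][name]
            arrays = {}
            for pname in g:
                arr = g[pname][...]
                if arr.dtype.itemsize != expected_width:
                    raise FormatError(
                        f"layer {name}/{pname}: {arr.dtype} payload does not match "
                        f"declared precision {precision}"
                    )
                arrays[pname] = arr
            state["layers"][name] = arrays
    return DiscriminatorModel.from_state_dict(state)


def load_config(path: str) -> dict:
    """Read a YAML pipeline configuration (must be a mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a YAML mapping")
    return cfg
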