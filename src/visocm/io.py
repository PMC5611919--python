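"""Raw-volume and image file formats.

Raw spectral volumes are stored as little-endian unsigned 16-bit binary in
A-scan-major order (x, y, pixel) with a JSON sidecar recording the
dimensions, the pixel-to-wavelength calibration, and the provenance
(seed, instrument, phantom).  Tomograms, en-face maps and attenuation
maps go to 32-bit float TIFF; surface maps to 16-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .reconstruct import SpectralVolume

RAW_NAME = "spectra.raw"
SIDECAR_NAME = "sidecar.json"


def write_spectral_volume(
    directory,
    volume: SpectralVolume,
    *,
    seed: int | None = None,
    instrument: dict | None = None,
    phantom: dict | None = None,
) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    counts = np.ascontiguousarray(volume.counts, dtype="<u2")
    counts.tofile(d / RAW_NAME)
    lam = volume.wavelengths_nm
    # linear calibration coefficients; full table kept when non-linear
    c1 = (lam[-1] - lam[0]) / (lam.size - 1)
    linear = np.allclose(lam, lam[0] + c1 * np.arange(lam.size), rtol=0, atol=1e-9)
    sidecar = {
        "nx": int(counts.shape[0]),
        "ny": int(counts.shape[1]),
        "n_pixels": int(counts.shape[2]),
        "bit_depth": int(volume.bit_depth),
        "byte_order": "little",
        "calibration": (
            {"kind": "linear", "c0": float(lam[0]), "c1": float(c1)}
            if linear
            else {"kind": "table", "wavelength_nm": lam.tolist()}
        ),
        "seed": seed,
        "instrument": instrument,
        "phantom": phantom,
    }
    (d / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return d


def read_spectral_volume(directory) -> SpectralVolume:
    d = Path(directory)
    sidecar_path = d / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    nx, ny, nk = meta["nx"], meta["ny"], meta["n_pixels"]
    raw = d / RAW_NAME
    expected = nx * ny * nk * 2
    actual = raw.stat().st_size
    if actual != expected:
        raise ValueError(
            f"raw payload is {actual} bytes but the header implies "
            f"{nx}x{ny}x{nk} u16 = {expected} bytes"
        )
    counts = np.fromfile(raw, dtype="<u2").reshape(nx, ny, nk)
    cal = meta["calibration"]
    if cal["kind"] == "linear":
        lam = cal["c0"] + cal["c1"] * np.arange(nk)
    else:
        lam = np.asarray(cal["wavelength_nm"], dtype=float)
    return SpectralVolume(counts=counts, wavelengths_nm=lam, bit_depth=meta["bit_depth"])


def write_float_tiff(path, array: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def write_surface_tiff(path, surface_index: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(surface_index, dtype=np.uint16))
    return path


def write_rgb_tiff(path, rgb01: np.ndarray) -> Path:
    """Write an RGB image (values in [0, 1]) as 8-bit colour TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(rgb01) * 255.0, 0, 255).astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB array")
    tifffile.imwrite(path, arr, photometric="rgb")
    return path
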