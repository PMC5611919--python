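"""Attenuation-coefficient estimation.

Two estimators of the total attenuation coefficient mu_t (mm^-1):

* **global** — a per-A-line exponential fit I(z) = I0 * exp(-mu_t * z)
  over a fixed depth window beneath the surface (Lambert decay).  The
  detected OCM intensity of a homogeneous scatterer distribution decays
  with the *round-trip* path, exp(-2 mu z); the ``roundtrip`` flag selects
  whether the fitted exponent is reported as-is ("single", the model
  verbatim) or halved ("double", the physical round-trip reading).

* **local** — the depth-resolved per-pixel estimator

      mu_t[i] = 1/(2 Delta) * ln(1 + I[i] / sum_{j>i} I[j])

  (natural logarithm; Delta is the axial pixel size in mm), which is
  exact for round-trip exponential decay with an untruncated tail.  The
  last pixel has an empty tail and is marked invalid (NaN); a zero tail
  under a nonzero pixel yields +inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .reconstruct import SurfaceMap, slab_pixel_range


@dataclass
class GlobalFitResult:
    mu_t: float
    i0: float
    fit_depth_range_mm: tuple
    residual: float
    valid: bool


@dataclass
class AttenuationVolume:
    """Per-pixel local attenuation (mm^-1) on a tomogram grid."""

    mu_local: np.ndarray  # (nx, ny, nz)
    axial_pitch_mm: float


def local_attenuation(intensity: np.ndarray, delta_mm: float) -> np.ndarray:
    """Depth-resolved per-pixel attenuation along the last axis.

    Returns an array of the same shape; the last pixel is NaN (empty
    tail), pixels whose tail sums to zero while the pixel itself is
    nonzero are +inf.
    """
    if delta_mm <= 0:
        raise ValueError("pixel size must be positive")
    I = np.asarray(intensity, dtype=float)
    if np.any(I < 0):
        raise ValueError("intensities must be nonnegative")
    # tail[j] = sum_{m > j} I[m]
    rev = np.flip(np.cumsum(np.flip(I, axis=-1), axis=-1), axis=-1)
    tail = rev - I
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.log1p(I / tail) / (2.0 * delta_mm)
    mu[..., -1] = np.nan
    zero_tail = tail <= 0
    mu[zero_tail & (I > 0)] = np.inf
    mu[zero_tail & (I <= 0)] = np.nan
    return mu


def fit_global_attenuation(
    ascan_intensity: np.ndarray,
    surface_index: int,
    fit_depth_mm: float = 0.2,
    delta_mm: float = 1e-3,
    roundtrip: str = "single",
) -> GlobalFitResult:
    """Fit I0 * exp(-mu * z) over a window beneath the surface.

    ``z`` is measured from the surface in mm.  A closed-form log-linear
    regression seeds one round of nonlinear least squares with fixed
    tolerances; windows shorter than 8 samples, or fits that fail, return
    ``valid=False`` instead of raising.  With ``roundtrip="double"`` the
    fitted decay rate is halved to report the single-pass mu of
    round-trip-decaying data.
    """
    if roundtrip not in ("single", "double"):
        raise ValueError("roundtrip must be 'single' or 'double'")
    I = np.asarray(ascan_intensity, dtype=float)
    n = I.size
    lo = int(surface_index)
    hi = min(n, lo + int(round(fit_depth_mm / delta_mm)))
    invalid = GlobalFitResult(np.nan, np.nan, (0.0, 0.0), np.nan, False)
    if lo < 0 or hi - lo < 8:
        return invalid
    y = I[lo:hi]
    z = np.arange(hi - lo) * delta_mm
    pos = y > 0
    if pos.sum() < 8:
        return invalid

    # log-linear seed (exact on noiseless exponentials)
    slope, intercept = np.polyfit(z[pos], np.log(y[pos]), 1)
    c0 = max(-slope, 0.0) if abs(slope) > 1e-300 else 0.0
    i0 = float(np.exp(intercept))
    try:
        popt, _ = curve_fit(
            lambda zz, a, c: a * np.exp(-c * zz),
            z,
            y,
            p0=(i0, -slope),
            maxfev=2000,
        )
        i0, c = float(popt[0]), float(popt[1])
    except RuntimeError:
        c = -slope  # keep the seed fit, flagged valid: it is well defined
    resid = float(np.sqrt(np.mean((y - i0 * np.exp(-c * z)) ** 2)) / max(y.max(), 1e-300))
    mu = c / 2.0 if roundtrip == "double" else c
    return GlobalFitResult(
        mu_t=mu,
        i0=i0,
        fit_depth_range_mm=(0.0, (hi - lo) * delta_mm),
        residual=resid,
        valid=bool(np.isfinite(mu)),
    )


def mean_aligned_ascan(intensity: np.ndarray, surface: SurfaceMap, n_keep: int | None = None):
    """Surface-aligned mean depth profile of a region.

    Shifts every valid A-line so its surface sits at index 0, then
    averages; returns (profile, n_lines).  Averaging before fitting
    suppresses speckle and comb ripple that defeat per-line fits on
    small fields.
    """
    nx, ny, nz = intensity.shape
    if n_keep is None:
        n_keep = nz - int(surface.surface_index[surface.valid_mask].max()) if surface.valid_mask.any() else 0
    if n_keep <= 0:
        raise ValueError("no depth samples remain after alignment")
    acc = np.zeros(n_keep)
    n = 0
    for ix in range(nx):
        for iy in range(ny):
            if not surface.valid_mask[ix, iy]:
                continue
            s = int(surface.surface_index[ix, iy])
            if s + n_keep <= nz:
                acc += intensity[ix, iy, s : s + n_keep]
                n += 1
    if n == 0:
        raise ValueError("no valid A-lines in the region")
    return acc / n, n


def fit_global_volume(
    intensity: np.ndarray,
    surface: SurfaceMap,
    fit_depth_mm: float = 0.2,
    delta_mm: float = 1e-3,
    roundtrip: str = "single",
) -> np.ndarray:
    """Per-A-line global fits over a volume; returns a structured array."""
    nx, ny, _ = intensity.shape
    out = np.zeros((nx, ny), dtype=[("mu", float), ("i0", float), ("residual", float), ("valid", bool)])
    for ix in range(nx):
        for iy in range(ny):
            if not surface.valid_mask[ix, iy]:
                out[ix, iy] = (np.nan, np.nan, np.nan, False)
                continue
            r = fit_global_attenuation(
                intensity[ix, iy],
                int(surface.surface_index[ix, iy]),
                fit_depth_mm,
                delta_mm,
                roundtrip,
            )
            out[ix, iy] = (r.mu_t, r.i0, r.residual, r.valid)
    return out


def attenuation_enface(
    att: AttenuationVolume | np.ndarray,
    surface: SurfaceMap,
    depth_start_um: float,
    depth_end_um: float,
    axial_pitch_um: float | None = None,
) -> np.ndarray:
    """Mean local attenuation over a surface-referenced slab per (x, y).

    Non-finite pixels (invalid last-pixel NaN, +inf sentinels) are
    excluded from the mean; A-lines with no valid pixel in the slab are
    NaN in the map.
    """
    if isinstance(att, AttenuationVolume):
        mu = att.mu_local
        pitch = att.axial_pitch_mm * 1e3
    else:
        mu = np.asarray(att)
        if axial_pitch_um is None:
            raise ValueError("axial_pitch_um is required for a bare array")
        pitch = axial_pitch_um
    nx, ny, nz = mu.shape
    out = np.full((nx, ny), np.nan)
    for ix in range(nx):
        for iy in range(ny):
            if not surface.valid_mask[ix, iy]:
                continue
            lo, hi, _ = slab_pixel_range(
                int(surface.surface_index[ix, iy]), depth_start_um, depth_end_um, pitch, nz
            )
            vals = mu[ix, iy, lo:hi]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[ix, iy] = vals.mean()
    return out
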