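"""Spectral-domain tomogram reconstruction.

Raw spectrometer counts, sampled uniformly in wavelength, are turned into a
depth-resolved complex tomogram per A-line:

    background removal -> resampling to uniform wavenumber k = 2*pi/lambda
    -> polynomial dispersion-phase correction -> FFT -> positive-depth half.

Wavelengths are in nm, wavenumbers in rad/um and depths in um throughout,
so a scatterer at optical depth z produces the fringe cos(2*k*z).  Also
provides threshold-based surface detection and surface-referenced en-face
mean projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.optimize import minimize


@dataclass
class SpectralVolume:
    """Raw per-A-line spectrometer counts with wavelength calibration."""

    counts: np.ndarray  # (nx, ny, n_pixels)
    wavelengths_nm: np.ndarray  # monotone pixel -> wavelength map
    bit_depth: int = 12

    def __post_init__(self):
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (nx, ny, n_pixels)")
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        d = np.diff(lam)
        if lam.size != self.counts.shape[-1]:
            raise ValueError("calibration length does not match spectral axis")
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength calibration must be strictly monotone")
        self.wavelengths_nm = lam

    @property
    def dims(self):
        return self.counts.shape


@dataclass(frozen=True)
class DispersionModel:
    """Polynomial dispersion phase exp(i * sum_j a_j (k - k0)^j), j >= 2.

    ``k0`` is the reference wavenumber (rad/um); ``coeffs`` holds
    (a2, a3, ..., a_p) in radians per (rad/um)^j, p <= 5.
    """

    k0: float
    coeffs: tuple = ()
    warning: str | None = None

    def __post_init__(self):
        if len(self.coeffs) > 4:
            raise ValueError("dispersion order is limited to 5")
        if not all(np.isfinite(c) for c in self.coeffs):
            raise ValueError("dispersion coefficients must be finite")

    def phase(self, k: np.ndarray) -> np.ndarray:
        dk = np.asarray(k, dtype=float) - self.k0
        phi = np.zeros_like(dk)
        for j, a in enumerate(self.coeffs, start=2):
            phi += a * dk**j
        return phi

    def negated(self) -> "DispersionModel":
        return DispersionModel(self.k0, tuple(-a for a in self.coeffs))


@dataclass
class Tomogram:
    """Depth-resolved complex field with its axial sampling."""

    field: np.ndarray  # complex, (nx, ny, nz)
    axial_pitch_um: float
    warning: str | None = None

    @property
    def intensity(self) -> np.ndarray:
        return self.field.real**2 + self.field.imag**2

    @property
    def n_depth(self) -> int:
        return self.field.shape[-1]

    @property
    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.n_depth) * self.axial_pitch_um


@dataclass
class SurfaceMap:
    surface_index: np.ndarray  # (nx, ny) int
    valid_mask: np.ndarray  # (nx, ny) bool


def wavelength_to_k(lam_nm: np.ndarray) -> np.ndarray:
    """k = 2*pi/lambda in rad/um for wavelengths in nm."""
    return 2.0e3 * math.pi / np.asarray(lam_nm, dtype=float)


def _axial_pitch_um(k_grid: np.ndarray) -> float:
    dk = k_grid[1] - k_grid[0]
    return math.pi / (len(k_grid) * dk)


def resample_to_k(spectrum: np.ndarray, wavelengths_nm: np.ndarray, n_out: int | None = None):
    """Resample spectra from a wavelength grid onto a uniform k grid.

    ``spectrum`` may be 1-D or (..., n_pixels).  Returns ``(k_grid,
    resampled)`` with ``k_grid`` ascending.  Cubic-spline interpolation is
    used on the monotone lambda -> k remap.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    if lam.size < 16:
        raise ValueError("at least 16 spectral samples are required")
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavelength calibration must be strictly monotone")
    if lam.size != spec.shape[-1]:
        raise ValueError("spectrum length does not match calibration")

    if d[0] < 0:  # make lambda ascending for the spline
        lam = lam[::-1]
        spec = spec[..., ::-1]

    n = n_out or lam.size
    k_grid = np.linspace(wavelength_to_k(lam[-1]), wavelength_to_k(lam[0]), n)
    lam_eval = 2.0e3 * math.pi / k_grid
    cs = CubicSpline(lam, spec, axis=-1)
    return k_grid, cs(lam_eval)


def remove_background(volume, background="estimate") -> np.ndarray:
    """Subtract the reference (DC) spectrum from every A-line.

    ``background`` is either a per-pixel reference spectrum or the string
    ``"estimate"``, in which case the mean spectrum over all A-lines of
    the volume is subtracted.  Returns float counts with the same shape.
    """
    counts = volume.counts if isinstance(volume, SpectralVolume) else np.asarray(volume)
    counts = counts.astype(float)
    if isinstance(background, str):
        if background != "estimate":
            raise ValueError(f"unknown background mode {background!r}")
        bg = counts.reshape(-1, counts.shape[-1]).mean(axis=0)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (counts.shape[-1],):
            raise ValueError(
                f"background length {bg.shape} does not match spectral axis "
                f"({counts.shape[-1]},)"
            )
    return counts - bg


def apply_dispersion(k_spectrum: np.ndarray, k_grid: np.ndarray, model: DispersionModel) -> np.ndarray:
    """Multiply a uniform-k spectrum by the unit-modulus dispersion phasor."""
    phasor = np.exp(1j * model.phase(k_grid))
    return np.asarray(k_spectrum) * phasor


def _corrected_k_spectra(volume: SpectralVolume, model=None, background="estimate"):
    """Shared front half of reconstruction.

    Returns ``(k_grid, spectra, envelope_k)`` where ``spectra`` is the
    complex background-corrected, dispersion-corrected stack of shape
    (nx*ny, nk) and ``envelope_k`` is the mean raw spectrum resampled to k
    (an estimate of the source envelope times the reference power).
    """
    nx, ny, nk = volume.dims
    corrected = remove_background(volume, background).reshape(nx * ny, nk)
    k_grid, spectra = resample_to_k(corrected, volume.wavelengths_nm)
    mean_raw = volume.counts.reshape(nx * ny, nk).mean(axis=0)
    _, envelope_k = resample_to_k(mean_raw, volume.wavelengths_nm)
    envelope_k = np.clip(envelope_k, 0.0, None)
    spectra = spectra.astype(complex)
    if model is not None:
        spectra = apply_dispersion(spectra, k_grid, model)
    return k_grid, spectra, envelope_k


def reconstruct(
    volume: SpectralVolume,
    model: DispersionModel | None = None,
    *,
    background="estimate",
    window: np.ndarray | None = None,
    pad_factor: int = 1,
    keep: str = "half",
) -> Tomogram:
    """Reconstruct a complex tomogram from a raw spectral volume.

    Per A-line: background removal, resampling to uniform k, dispersion
    correction, optional spectral window (uniform-k gain), FFT.  By
    default the positive-depth half of the transform is kept; ``keep=
    "full"`` retains all bins (for energy checks).  ``pad_factor`` zero-
    pads the FFT for sub-pixel depth sampling.
    """
    nx, ny, nk = volume.dims
    k_grid, spectra, _ = _corrected_k_spectra(volume, model=model, background=background)
    if window is not None:
        spectra = spectra * np.asarray(window)[None, :]
    n_fft = nk * int(pad_factor)
    ascans = np.fft.fft(spectra, n=n_fft, axis=-1)
    if keep == "half":
        ascans = ascans[:, : n_fft // 2]
    elif keep != "full":
        raise ValueError("keep must be 'half' or 'full'")
    pitch = _axial_pitch_um(k_grid) / pad_factor
    return Tomogram(field=ascans.reshape(nx, ny, -1), axial_pitch_um=pitch)


def estimate_dispersion(
    volume: SpectralVolume,
    order: int = 3,
    search_bounds=((-15.0, 15.0), (-8.0, 8.0)),
    *,
    n_grid: int = 13,
    max_lines: int = 64,
    background="estimate",
) -> DispersionModel:
    """Estimate dispersion-mismatch coefficients from image sharpness.

    Minimises the Shannon entropy of the normalised reconstructed
    intensity over a deterministic subset of A-lines: a coarse grid over
    (a2, a3) followed by Nelder-Mead refinement from the best grid node
    with fixed tolerances, so the result is reproducible.  Coefficients
    beyond a3 (orders 4, 5) start at zero in the refinement.
    """
    if order < 2 or order > 5:
        raise ValueError("dispersion order must be in 2..5")
    nx, ny, nk = volume.dims
    corrected = remove_background(volume, background).reshape(nx * ny, nk)
    stride = max(1, corrected.shape[0] // max_lines)
    lines = corrected[::stride]
    k_grid, spectra = resample_to_k(lines, volume.wavelengths_nm)
    k0 = float(k_grid.mean())
    dk = k_grid - k0
    nz = nk // 2

    powers = [dk**j for j in range(2, order + 1)]

    def entropy(coeffs):
        phi = np.zeros_like(dk)
        for a, p in zip(coeffs, powers):
            phi += a * p
        ascans = np.fft.fft(spectra * np.exp(1j * phi)[None, :], axis=-1)[:, :nz]
        inten = ascans.real**2 + ascans.imag**2
        total = inten.sum()
        if total <= 0:
            return np.inf
        p_ = inten / total
        nzmask = p_ > 0
        return float(-(p_[nzmask] * np.log(p_[nzmask])).sum())

    # coarse deterministic grid over the first two coefficients
    b2 = np.linspace(*search_bounds[0], n_grid)
    b3 = np.linspace(*search_bounds[1], n_grid) if order >= 3 else np.array([0.0])
    best, best_e = None, np.inf
    for a2 in b2:
        for a3 in b3:
            c = [a2] + ([a3] if order >= 3 else []) + [0.0] * (order - 3 if order > 3 else 0)
            e = entropy(c)
            if e < best_e:
                best, best_e = c, e

    res = minimize(
        entropy,
        x0=np.asarray(best, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 600},
    )
    coeffs = tuple(float(c) for c in res.x)
    warning = None if res.success else "optimizer did not converge"
    return DispersionModel(k0=k0, coeffs=coeffs, warning=warning)


def detect_surface(
    tomogram: Tomogram,
    threshold_sd: float = 4.0,
    smoothing_px: int = 5,
    *,
    min_index: int = 2,
    consecutive_px: int = 3,
    min_fraction_of_max: float = 0.05,
) -> SurfaceMap:
    """Locate the sample surface along every A-line.

    The noise floor is estimated per A-line from the deepest 10% of
    samples; the surface is the first depth (>= ``min_index``) where the
    intensity exceeds mean + ``threshold_sd`` * sd for ``consecutive_px``
    consecutive pixels (guards against single-bin noise spikes).  The
    threshold is additionally floored at ``min_fraction_of_max`` times
    the A-line's own peak so that the weak sample-sample interference
    pedestal near zero delay is not mistaken for tissue.  The index map
    is median-smoothed with a ``smoothing_px`` window; A-lines that never
    cross the threshold are flagged invalid.
    """
    inten = tomogram.intensity
    nx, ny, nz = inten.shape
    n_noise = max(4, nz // 10)
    tail = inten[..., -n_noise:]
    thr = tail.mean(axis=-1) + threshold_sd * tail.std(axis=-1)
    thr = np.maximum(thr, min_fraction_of_max * inten[..., min_index:].max(axis=-1))

    above = inten[..., min_index:] > thr[..., None]
    if consecutive_px > 1:
        run = above.copy()
        for s in range(1, consecutive_px):
            run[..., : -(s)] &= above[..., s:]
            run[..., -(s):] = False
        above = run
    any_hit = above.any(axis=-1)
    first = above.argmax(axis=-1) + min_index

    surface = first.astype(np.int64)
    valid = any_hit
    if valid.any() and smoothing_px > 1:
        fill = int(np.median(surface[valid]))
        tmp = np.where(valid, surface, fill)
        surface = median_filter(tmp, size=smoothing_px, mode="nearest")
    return SurfaceMap(surface_index=surface, valid_mask=valid)


def slab_pixel_range(surface_idx: int, depth_start_um: float, depth_end_um: float, pitch_um: float, nz: int):
    """Half-open pixel interval for a surface-referenced depth slab.

    Start rounds down, end rounds up, clipped to [0, nz); returns
    (start, end, truncated).
    """
    if depth_end_um <= depth_start_um:
        raise ValueError("depth_end must exceed depth_start")
    lo = surface_idx + int(math.floor(depth_start_um / pitch_um))
    hi = surface_idx + int(math.ceil(depth_end_um / pitch_um))
    truncated = hi > nz or lo < 0
    return max(lo, 0), min(hi, nz), truncated


def enface_projection(
    tomogram,
    surface: SurfaceMap,
    depth_start_um: float,
    depth_end_um: float,
    statistic: str = "mean",
) -> np.ndarray:
    """Mean-intensity en-face projection over a surface-referenced slab.

    ``tomogram`` may be a Tomogram or a plain 3-D array plus pitch via
    Tomogram only.  Invalid A-lines are NaN in the output.
    """
    if statistic != "mean":
        raise ValueError("only the mean projection is supported")
    inten = tomogram.intensity if isinstance(tomogram, Tomogram) else np.asarray(tomogram)
    pitch = tomogram.axial_pitch_um
    nx, ny, nz = inten.shape
    out = np.full((nx, ny), np.nan)
    for ix in range(nx):
        for iy in range(ny):
            if not surface.valid_mask[ix, iy]:
                continue
            lo, hi, _ = slab_pixel_range(
                int(surface.surface_index[ix, iy]), depth_start_um, depth_end_um, pitch, nz
            )
            if hi > lo:
                out[ix, iy] = inten[ix, iy, lo:hi].mean()
    return out


def peak_fwhm(profile: np.ndarray, dx: float = 1.0) -> float:
    """FWHM of the dominant peak via linear interpolation at half maximum."""
    y = np.asarray(profile, dtype=float)
    ip = int(np.argmax(y))
    half = y[ip] / 2.0
    lo = ip
    while lo > 0 and y[lo] > half:
        lo -= 1
    hi = ip
    while hi < y.size - 1 and y[hi] > half:
        hi += 1
    # linear interpolation of the crossings
    xl = lo + (half - y[lo]) / (y[lo + 1] - y[lo]) if y[lo + 1] != y[lo] else lo
    xr = hi - (half - y[hi]) / (y[hi - 1] - y[hi]) if y[hi - 1] != y[hi] else hi
    return float((xr - xl) * dx)
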