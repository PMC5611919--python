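# Methods

## Forward model

The simulator emulates a spectrometer-based visible-light OCM: a
Gaussian source (centre 555 nm, FWHM 156 nm) truncated to the detected
band 425–685 nm, weighted by a piecewise-linear CMOS quantum-efficiency
curve, detected on a wavelength-linear pixel grid (default 8192 pixels,
reducible).  The sample is a sparse sum of sub-resolution scatterers:
per A-line

    I(k) = env(λ) · | r + Σⱼ aⱼ(λ) e^{i(2 k zⱼ + φ(k))} |²

with reference amplitude r, optical depths zⱼ = z₀ + surface +
n·(depth − surface) for group index n = 1.36, and an optional injected
dispersion phase φ(k) = Σ aⱼ(k−k₀)ʲ.  Scatterer amplitudes carry

* the layer backscatter level and a (λ/555)^s power-law slope, or an
  inclusion-specific profile (a logistic long-pass emulates the
  red-preferential contrast of an amyloid stain);
* single-pass-in-amplitude Lambert attenuation exp(−∫μ dz), i.e.
  round-trip exp(−2∫μ dz) in intensity — the convention under which the
  per-pixel estimator is exact;
* Gaussian-in-λ absorption bands (the 550-nm absorber default strength,
  20 mm⁻¹, is of the order of whole-blood haemoglobin absorption, so
  the absorbing bands decay within the recorded depth range);
* exponential sensitivity roll-off at 24 dB/mm (in intensity),
  wavelength-independent.

Noise: Gaussian shot term with sd = shot_scale·√counts (shot_scale
0.15 ≈ 1/√50 for ~50 electrons per camera count), multiplicative
excess-intensity noise (sd 0.02, mimicking supercontinuum RIN), read
noise (0.5 counts), then 12-bit quantisation.  All randomness flows
from explicit seeds; identical inputs give bit-identical volumes.

Two placement modes: Poisson-random depths with Rayleigh amplitudes
(speckle statistics, for qualitative scenes) and a *regular* mode —
fixed amplitudes on a regular axial grid with one uniform per-line
offset — which is speckle-free and supports clean parameter-recovery
studies on desk-scale fields, at the cost of a stronger deterministic
autocorrelation pedestal near zero delay and a weak Moiré ripple
against the depth grid.

## What the generator does not emulate

Fully developed speckle statistics are only approximated; there is no
confocal (depth-of-focus) gating (focus assumed at the surface), no
polarisation, no motion, and clearing chemistry is reduced to a
multiplicative decrease of layer backscatter and attenuation.  Passing
tests therefore demonstrate correctness of the *processing*, not
instrument-level realism.

## Reconstruction

Stage order: background removal (supplied reference spectrum, or the
mean spectrum over all A-lines — both equivalent before/after
resampling because spline interpolation is linear), cubic-spline
resampling from the monotone λ grid onto a uniform k grid spanning the
same band, dispersion correction, FFT, positive-depth half.  The axial
pitch is π/(n·δk) (optical depth); conversion to geometric depth
divides by the group index 1.36 only where stated.

Dispersion coefficients are estimated by minimising the Shannon entropy
of the normalised reconstructed intensity over a deterministic A-line
subset: a coarse grid over (a₂, a₃) followed by Nelder–Mead with fixed
tolerances, so the estimate is reproducible.  On a simulated point
target with |a₂| up to ~50 rad over the band the corrected PSF is
within 10% of the transform limit.

Surface detection thresholds each A-line at noise mean + 4 sd (noise
from the deepest 10% of samples), requires 3 consecutive supra-
threshold pixels, and floors the threshold at 5% of the A-line peak —
the latter because the sample-sample interference pedestal near zero
delay, though 20+ dB below tissue, can exceed a purely noise-based
threshold.  The index map is median-smoothed (5 px).  Depth slabs are
half-open pixel intervals (floor of start, ceiling of end).

### Sampling-induced limits

With the full band sampled on n wavelength-linear pixels, the blue end
of the spectrum is the first to alias: fringes are usable only up to
optical depth ≈ λ_min²/(4 dλ) (≈177 μm at 1024 pixels, doubling with
n).  Desk-scale phantoms therefore stay within ~100 μm geometric
extent.  Resampling with equal point counts also oversamples the blue
end (factor λ_c²/λ_min² ≈ 1.6), which low-pass-filters detector noise
there; the resulting depth-decaying noise floor mildly inflates
blue-band attenuation estimates.  Both effects are properties of real
λ-sampled spectrometers, mitigated there by much denser sampling.

## Spectroscopic windows

Windows are Gaussian in wavelength (per the constant-Δz design
equations) and applied in the k domain at λ(k).  Energy equalisation
anchors every windowed source-envelope area to window 1; the envelope
is estimated as the mean raw spectrum of the volume.  Roll-off
compensation multiplies each sub-band intensity A-scan by the inverse
exponential roll-off gain.  RGB composition log-compresses each channel
over a 40-dB dynamic range below the common peak, so equal band
intensities render grey/white.  Channel splitting demands ±2σ supports
(σ = FWHM/2.355) to be disjoint — a concrete proxy for "non-overlapping
windows".

`spectral_profiles` crops each sub-band A-scan to 100 μm below the
deepest surface before applying the per-pixel attenuation estimator:
its tail sum must run over the imaged tissue range, because a tail of
thousands of empty noise bins otherwise drowns the tissue term.

## Attenuation estimators

The global fit seeds a log-linear regression (exact on noiseless data)
and refines with one round of nonlinear least squares at fixed
tolerances; windows shorter than 8 samples return an invalid flag
rather than raising.  The per-pixel estimator uses the natural
logarithm; the last pixel (empty tail) is NaN and a zero tail under a
nonzero pixel returns +inf, both excluded from en-face means.

The two estimators use different round-trip conventions as printed —
the global model has no factor 2, the local model divides by 2Δ.  A
`roundtrip={"single","double"}` flag on the global fit reconciles them:
simulated intensity decays with the round trip, so end-to-end
comparisons use `"double"`, and on noiseless single-exponential volumes
the two estimators then agree within 1%.

Quantitative recovery studies fit the surface-aligned *mean* A-scan of
a region (the regular, speckle-free medium) rather than per-line fits:
at desk-scale fields speckle noise in a 100-μm window otherwise
dominates a 0.04 mm⁻¹ WM/GM contrast.  The default global-fit window is
200 μm below the surface (configurable); the desk-scale analyses use
100 μm to stay inside the alias-free depth range.

## Statistics

Welch two-sample t-tests by default (pooled variance optional),
Bonferroni adjustment p_adj = min(1, m·p) over the m unordered pairs,
significance at adjusted p < 0.05.  Intensity comparisons run on the
dB scale by default in the analysis scripts (display practice; linear
available).  Region sampling draws a seeded uniform subsample without
replacement when a region holds more voxels than requested.  Identical
zero-variance groups take the p = 1 path.  The clearing time course
normalises every mean amplitude by the pre-clearing value and fits a
least-squares line through the normalised means.

## Problem sizes

Tests simulate 10–16 A-lines per side with 512–2048 spectral pixels;
the analysis scripts use up to 24×16 A-lines × 2048 pixels.  The full
500×500×8192 geometry is supported by the same code paths but exercised
nowhere in the repository; the desk-scale sizes were chosen so the
whole suite runs in well under a minute while leaving every stage's
behaviour measurable.

## Known limitations

* Per-A-line global fits on speckled desk-scale data are noisy
  (sd ≈ 0.2–0.3 mm⁻¹); region-mean profiles are the supported route to
  quantitative μ at these field sizes.
* The per-pixel estimator is biased upward where its (cropped) tail is
  truncated and downward where the tail is noise-dominated; absolute
  values in the seven-window profiles are therefore relative, and only
  their ordering across bands is interpreted.
* The energy-equalisation anchor (window 1) is one of several
  reasonable conventions; the recorded normalisation makes the choice
  explicit.
* Whether roll-off compensation should act per sub-band or on the full
  band is ambiguous; it is applied per sub-band here, with the rate a
  configurable input.
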