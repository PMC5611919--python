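# visocm — spectroscopic visible-light OCM analysis

`visocm` is an analysis pipeline for spectral-domain visible-light
optical coherence microscopy (OCM) of brain tissue.  Visible-light OCM
reaches sub-micrometre axial resolution and, because its band spans
425–685 nm, supports *spectroscopic* imaging: reconstructing the same
scene through several wavelength sub-bands to separate white matter
(WM), grey matter (GM) and amyloid-beta plaques by their backscatter
spectrum and attenuation.  No instrument is required: a synthetic
interferogram generator with full ground truth stands in for the
spectrometer, so every processing stage is verifiable from a seed.

## What the package computes

**Reconstruction.**  Raw spectrometer counts (uniform in wavelength λ)
are background-subtracted, resampled to uniform wavenumber k = 2π/λ,
corrected with a polynomial dispersion phase exp(i·Σ aⱼ(k−k₀)ʲ) whose
coefficients are estimated by entropy minimisation, and Fourier
transformed into depth profiles.  Surface detection and surface-
referenced en-face mean projections follow.

**Constant-resolution Gaussian windows.**  A band centred at λᵢ with
FWHM Δλᵢ reconstructs with axial resolution

    Δz = (2 ln 2 / π) · λᵢ² / Δλᵢ .

Given the source FWHM Δλ_t and N window centres, the bandwidths

    Δλ₁ = Δλ_t / (1 + (1/λ₁²) Σ_{i≥2} λᵢ²),   Δλ_{i+1} = (λ_{i+1}²/λᵢ²) Δλᵢ

make Δz identical across bands, and Σᵢ Δλᵢ = Δλ_t exactly.  Sub-spectra
are energy-equalised, roll-off compensated, and composed into RGB
(three bands) or two fully independent channels (disjoint bands).

**Attenuation.**  Per A-scan, the Lambert decay I(z) = I₀·exp(−μ_t z)
is fitted over a window beneath the surface (global μ_t); per pixel,
the depth-resolved estimator

    μ_t[i] = 1/(2Δ) · ln(1 + I[i] / Σ_{j>i} I[j])

gives local attenuation maps (Δ = axial pixel size in mm).

**Statistics.**  Seeded region sampling, intensity-vs-attenuation
cluster summaries, Welch t-tests with Bonferroni correction, and a
normalised amplitude time course for optical-clearing experiments.

## Worked example

```python
import visocm as v

ws = v.design_windows(156.0, [520.0, 560.0, 600.0])
print([round(f) for f in ws.fwhms_nm], round(ws.axial_resolution_um, 1))
```

prints `[45, 52, 59] 2.7`: splitting a 156-nm-FWHM visible spectrum at
520/560/600 nm requires 45/52/59-nm windows, each reconstructing with
the same 2.7 μm axial resolution.

The numbered scripts under `analysis/` run the full study on simulated
scenes (raw volumes land in `scratch/`, tables in `results/`):

```
python analysis/02_simulate_phantoms.py
python analysis/04_attenuation.py
```

prints, for the two-region cortex scene,

```
WM: fitted mu = 0.391/mm (truth 0.39/mm, 192 A-lines)
GM: fitted mu = 0.355/mm (truth 0.35/mm, 192 A-lines)
```

i.e. the exponential fit on the reconstructed, roll-off-compensated
volume recovers the ground-truth attenuation of the white- and
grey-matter-like halves to a few percent, with the WM half both
brighter and more strongly attenuating — the contrast that separates
the two tissue classes.

A thin CLI mirrors the library: `specoct simulate | reconstruct |
windows | run --config <yaml>`.

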