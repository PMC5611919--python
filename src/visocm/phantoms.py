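"""Preset brain-like phantom scenes.

These builders encode the study conditions the pipeline is exercised
under: white-matter-like (mu = 0.39 mm^-1, strong backscatter) versus
grey-matter-like (mu = 0.35 mm^-1) tissue, hyperscattering amyloid-like
inclusions of a few tens of micrometres, a Congo-red-like red-preferential
spectral contrast, a 550-nm absorption band, and a clearing time series
modelled as stepwise-reduced backscatter and attenuation.
"""

from __future__ import annotations

import numpy as np

from .synthetic import (
    AbsorptionPeak,
    GroundTruth,
    Inclusion,
    Layer,
    PhantomSpec,
    build_phantom,
)

WM_MU = 0.39  # mm^-1
GM_MU = 0.35  # mm^-1


def concat_truths(a: GroundTruth, b: GroundTruth) -> GroundTruth:
    """Stitch two voxelised scenes side by side along x."""
    if a.axial_step_um != b.axial_step_um or a.axial_extent_um != b.axial_extent_um:
        raise ValueError("scenes must share the axial grid")
    if a.spec.lateral_shape[1] != b.spec.lateral_shape[1]:
        raise ValueError("scenes must share ny")
    nx_a = a.spec.lateral_shape[0]
    nx = nx_a + b.spec.lateral_shape[0]
    ny = a.spec.lateral_shape[1]
    spec = PhantomSpec(
        lateral_shape=(nx, ny),
        lateral_pitch_um=a.spec.lateral_pitch_um,
        layers=a.spec.layers,
        refractive_index=a.spec.refractive_index,
        placement_seed=a.spec.placement_seed,
    )
    n_prof_a = len(a.profiles)
    nb_bands = max(len(a.abs_bands), len(b.abs_bands))

    def pad(od, n):
        out = np.zeros((od.shape[0], n))
        out[:, : od.shape[1]] = od
        return out

    return GroundTruth(
        spec=spec,
        axial_step_um=a.axial_step_um,
        axial_extent_um=a.axial_extent_um,
        true_mu_volume=np.concatenate([a.true_mu_volume, b.true_mu_volume], axis=0),
        true_surface=np.concatenate([a.true_surface, b.true_surface], axis=0),
        surface_um=np.concatenate([a.surface_um, b.surface_um], axis=0),
        scat_x=np.concatenate([a.scat_x, b.scat_x + nx_a]),
        scat_y=np.concatenate([a.scat_y, b.scat_y]),
        scat_z_um=np.concatenate([a.scat_z_um, b.scat_z_um]),
        scat_amp=np.concatenate([a.scat_amp, b.scat_amp]),
        scat_profile_id=np.concatenate([a.scat_profile_id, b.scat_profile_id + n_prof_a]),
        profiles=a.profiles + b.profiles,
        scat_abs_od=np.concatenate(
            [pad(a.scat_abs_od, nb_bands), pad(b.scat_abs_od, nb_bands)], axis=0
        ),
        abs_bands=a.abs_bands if len(a.abs_bands) >= len(b.abs_bands) else b.abs_bands,
    )


def homogeneous_tissue(
    mu_mm: float,
    backscatter: float = 0.01,
    *,
    lateral_shape=(16, 16),
    surface_um: float = 10.0,
    extent_um: float = 100.0,
    step_um: float = 2.0,
    density_um: float = 0.8,
    spectral_slope: float = 0.0,
    absorption_peaks=(),
    placement_seed: int = 0,
    tilt=(0.0, 0.0),
    regular: bool = False,
) -> GroundTruth:
    """One homogeneous scattering layer below a flat (or tilted) surface.

    ``regular`` places fixed-amplitude scatterers on a regular axial grid
    (speckle-free medium) for clean parameter-recovery studies.
    """
    spec = PhantomSpec(
        lateral_shape=lateral_shape,
        layers=(
            Layer(
                top_depth_um=surface_um,
                attenuation_mm=mu_mm,
                backscatter_level=backscatter,
                spectral_slope=spectral_slope,
                absorption_peaks=tuple(absorption_peaks),
                scatterer_density_um=density_um,
            ),
        ),
        surface_tilt=tilt,
        placement_seed=placement_seed,
        regular_spacing=regular,
    )
    return build_phantom(spec, extent_um, step_um)


def cortex_two_region(
    *,
    nx_half: int = 12,
    ny: int = 16,
    surface_um: float = 10.0,
    extent_um: float = 100.0,
    step_um: float = 2.0,
    placement_seed: int = 0,
    regular: bool = False,
) -> GroundTruth:
    """White matter (left, mu=0.39, bright) next to grey matter (right, mu=0.35)."""
    wm = homogeneous_tissue(
        WM_MU,
        backscatter=0.014,
        lateral_shape=(nx_half, ny),
        surface_um=surface_um,
        extent_um=extent_um,
        step_um=step_um,
        placement_seed=placement_seed,
        regular=regular,
    )
    gm = homogeneous_tissue(
        GM_MU,
        backscatter=0.008,
        lateral_shape=(nx_half, ny),
        surface_um=surface_um,
        extent_um=extent_um,
        step_um=step_um,
        placement_seed=placement_seed + 1,
        regular=regular,
    )
    return concat_truths(wm, gm)


def plaque_phantom(
    *,
    lateral_shape=(20, 20),
    surface_um: float = 10.0,
    extent_um: float = 100.0,
    step_um: float = 2.0,
    congo_red: bool = True,
    plaque_radius_um: float = 15.0,
    placement_seed: int = 0,
) -> GroundTruth:
    """Grey-matter-like tissue with hyperscattering amyloid-like inclusions.

    With ``congo_red`` the inclusions carry a red-preferential (long-pass)
    spectral profile emulating the stain; otherwise they are spectrally
    neutral hyperscatterers.
    """
    nx, ny = lateral_shape
    pitch = 2.0
    profile = {"longpass": 575.0, "width": 12.0} if congo_red else {"slope": 0.0}
    cx = nx * pitch / 2.0
    cy = ny * pitch / 2.0
    spec = PhantomSpec(
        lateral_shape=lateral_shape,
        lateral_pitch_um=pitch,
        layers=(
            Layer(
                top_depth_um=surface_um,
                attenuation_mm=GM_MU,
                backscatter_level=0.006,
                scatterer_density_um=0.8,
            ),
        ),
        inclusions=(
            Inclusion(
                center_um=(cx, cy, surface_um + 40.0),
                radius_um=plaque_radius_um,
                backscatter_gain=6.0,
                spectral_profile=profile,
            ),
        ),
        placement_seed=placement_seed,
    )
    return build_phantom(spec, extent_um, step_um)


def absorber_phantom(
    *,
    lateral_shape=(16, 16),
    peak_nm: float = 550.0,
    width_nm: float = 60.0,
    strength_mm: float = 20.0,
    placement_seed: int = 0,
) -> GroundTruth:
    """Homogeneous tissue with a haemoglobin-like absorption band.

    The default peak strength is of the order of whole-blood haemoglobin
    absorption near 550 nm, strong enough that the absorbing bands decay
    within the recorded depth range.
    """
    return homogeneous_tissue(
        GM_MU,
        backscatter=0.01,
        lateral_shape=lateral_shape,
        absorption_peaks=(AbsorptionPeak(peak_nm, width_nm, strength_mm),),
        placement_seed=placement_seed,
    )


def clearing_series(
    n_steps: int = 5,
    *,
    lateral_shape=(12, 12),
    backscatter0: float = 0.012,
    mu0: float = 0.5,
    reduction_per_step: float = 0.75,
    placement_seed: int = 0,
):
    """Time series of scenes with stepwise-reduced backscatter and mu.

    Optical clearing is emulated only as a multiplicative reduction of the
    layer backscatter and attenuation at each step; geometry is fixed.
    """
    truths = []
    for i in range(n_steps):
        f = reduction_per_step**i
        truths.append(
            homogeneous_tissue(
                mu0 * f,
                backscatter=backscatter0 * f,
                lateral_shape=lateral_shape,
                placement_seed=placement_seed,  # same scatterer layout each step
            )
        )
    return truths
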