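"""Configuration, orchestration and run manifests.

A pipeline run is fully described by one validated config (YAML or JSON):
instrument, phantom preset, window design, dispersion handling, slab and
region definitions, seeds and the output directory.  ``run_pipeline``
executes simulate -> reconstruct -> spectroscopy -> attenuation -> stats
and writes a manifest with the config hash and a SHA-256 checksum per
output file, so identical configs are verifiably reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import phantoms
from .atten import attenuation_enface, fit_global_volume, local_attenuation
from .io import (
    write_float_tiff,
    write_rgb_tiff,
    write_spectral_volume,
    write_surface_tiff,
)
from .reconstruct import detect_surface, enface_projection, estimate_dispersion, reconstruct
from .regionstats import RegionSpec, compare_groups, extract_region
from .spectro import apply_windows, compose_rgb, design_windows
from .synthetic import InstrumentSpec, NoiseModel, simulate_volume

_PRESETS = {
    "cortex_two_region": phantoms.cortex_two_region,
    "plaque_congo_red": phantoms.plaque_phantom,
    "absorber_550": phantoms.absorber_phantom,
}

_DEFAULTS = {
    "phantom": "cortex_two_region",
    "n_spectral_pixels": 1024,
    "windows": {"total_fwhm_nm": 156.0, "centers_nm": [520.0, 560.0, 600.0]},
    "dispersion": "none",  # none | auto | [a2, a3, ...]
    "enface_slab_um": [0.0, 100.0],
    "fit_depth_um": 200.0,
    "stats": True,
    "noise": {"shot_scale": 1.0, "excess_intensity_noise_sd": 0.02, "read_noise_sd": 1.0},
}

_REQUIRED = {"seed", "out_dir"}
_KNOWN = _REQUIRED | set(_DEFAULTS)


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    phantom: str = "cortex_two_region"
    n_spectral_pixels: int = 1024
    windows: dict = field(default_factory=lambda: dict(_DEFAULTS["windows"]))
    dispersion: object = "none"
    enface_slab_um: tuple = (0.0, 100.0)
    fit_depth_um: float = 200.0
    stats: bool = True
    noise: dict = field(default_factory=lambda: dict(_DEFAULTS["noise"]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enface_slab_um"] = list(d["enface_slab_um"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _validate(raw: dict) -> PipelineConfig:
    unknown = set(raw) - _KNOWN
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    missing = _REQUIRED - set(raw)
    if missing:
        raise ValueError(f"missing required config key(s): {sorted(missing)}")
    merged = {**_DEFAULTS, **raw}

    win = merged["windows"]
    centers = [float(c) for c in win["centers_nm"]]
    if any(b <= a for a, b in zip(centers, centers[1:])):
        raise ValueError(
            "windows.centers_nm must be strictly increasing (blue to red)"
        )
    if float(win["total_fwhm_nm"]) <= 0:
        raise ValueError("windows.total_fwhm_nm must be positive")
    if merged["phantom"] not in _PRESETS:
        raise ValueError(
            f"phantom must be one of {sorted(_PRESETS)}, got {merged['phantom']!r}"
        )
    slab = merged["enface_slab_um"]
    if len(slab) != 2 or slab[1] <= slab[0]:
        raise ValueError("enface_slab_um must be [start_um, end_um] with end > start")
    disp = merged["dispersion"]
    if not (disp in ("none", "auto") or isinstance(disp, (list, tuple))):
        raise ValueError("dispersion must be 'none', 'auto' or a coefficient list")

    return PipelineConfig(
        seed=int(merged["seed"]),
        out_dir=str(merged["out_dir"]),
        phantom=merged["phantom"],
        n_spectral_pixels=int(merged["n_spectral_pixels"]),
        windows={"total_fwhm_nm": float(win["total_fwhm_nm"]), "centers_nm": centers},
        dispersion=disp if isinstance(disp, str) else [float(c) for c in disp],
        enface_slab_um=(float(slab[0]), float(slab[1])),
        fit_depth_um=float(merged["fit_depth_um"]),
        stats=bool(merged["stats"]),
        noise={k: float(v) for k, v in merged["noise"].items()},
    )


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return _validate(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    return _validate(dict(raw))


def save_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    stages: dict
    timestamp: float

    def to_dict(self):
        return {"config_hash": self.config_hash, "stages": self.stages, "timestamp": self.timestamp}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full demo pipeline for one config.

    Stage order: simulate, reconstruct, spectroscopy, attenuation, stats
    (stats optional).  Any stage failure raises with the stage named.
    All randomness flows from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    def record(stage: str, paths: list[Path]):
        stages[stage] = {str(p.relative_to(out)): _sha256(p) for p in paths}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------
    def _simulate():
        truth = _PRESETS[config.phantom](placement_seed=config.seed)
        instrument = InstrumentSpec(
            n_spectral_pixels=config.n_spectral_pixels,
            noise=NoiseModel(**config.noise),
        )
        vol = simulate_volume(truth, instrument, seed=config.seed)
        d = write_spectral_volume(
            out / "raw",
            vol,
            seed=config.seed,
            instrument=instrument.to_dict(),
            phantom={"preset": config.phantom},
        )
        write_float_tiff(out / "truth" / "mu.tiff", truth.true_mu_volume)
        record("simulate", [d / "spectra.raw", d / "sidecar.json", out / "truth" / "mu.tiff"])
        return truth, instrument, vol

    truth, instrument, vol = run_stage("simulate", _simulate)

    # --- reconstruct --------------------------------------------------
    def _reconstruct():
        if config.dispersion == "auto":
            model = estimate_dispersion(vol)
        elif config.dispersion == "none":
            model = None
        else:
            from .reconstruct import DispersionModel

            k0 = float(np.mean(2.0e3 * np.pi / vol.wavelengths_nm))
            model = DispersionModel(k0=k0, coeffs=tuple(config.dispersion))
        tom = reconstruct(vol, model)
        surface = detect_surface(tom)
        enface = enface_projection(tom, surface, *config.enface_slab_um)
        paths = [
            write_float_tiff(out / "recon" / "intensity.tiff", tom.intensity),
            write_surface_tiff(out / "recon" / "surface.tiff", surface.surface_index),
            write_float_tiff(out / "recon" / "enface.tiff", enface),
        ]
        record("reconstruct", paths)
        return model, tom, surface

    model, tom, surface = run_stage("reconstruct", _reconstruct)

    # --- spectroscopy -------------------------------------------------
    def _spectro():
        ws = design_windows(config.windows["total_fwhm_nm"], config.windows["centers_nm"])
        sub = apply_windows(vol, ws, model, compensate_rolloff=True,
                            rolloff_db_per_mm=instrument.rolloff_db_per_mm)
        paths = [(out / "spectro" / "windows.json")]
        paths[0].parent.mkdir(parents=True, exist_ok=True)
        paths[0].write_text(json.dumps(ws.to_dict(), indent=1))
        for i, inten in enumerate(sub.intensities):
            paths.append(write_float_tiff(out / "spectro" / f"band_{i}.tiff", inten))
        if sub.n_windows == 3:
            rgb = compose_rgb(sub)
            mid = rgb.shape[1] // 2
            paths.append(write_rgb_tiff(out / "spectro" / "rgb_bscan.tiff",
                                        rgb[:, mid].transpose(1, 0, 2)))
        record("spectroscopy", paths)
        return sub

    sub = run_stage("spectroscopy", _spectro)

    # --- attenuation --------------------------------------------------
    def _atten():
        delta_mm = tom.axial_pitch_um * 1e-3
        inten = tom.intensity
        if instrument.rolloff_db_per_mm > 0:
            z_mm = np.arange(inten.shape[-1]) * delta_mm
            inten = inten * 10.0 ** (instrument.rolloff_db_per_mm * z_mm / 10.0)
        mu_local = local_attenuation(inten, delta_mm)
        en = attenuation_enface(mu_local, surface, *config.enface_slab_um,
                                axial_pitch_um=tom.axial_pitch_um)
        fits = fit_global_volume(inten, surface, config.fit_depth_um * 1e-3,
                                 delta_mm, roundtrip="double")
        import pandas as pd

        nx, ny = fits.shape
        df = pd.DataFrame(
            {
                "x": np.repeat(np.arange(nx), ny),
                "y": np.tile(np.arange(ny), nx),
                "mu": fits["mu"].ravel(),
                "i0": fits["i0"].ravel(),
                "residual": fits["residual"].ravel(),
                "valid": fits["valid"].ravel(),
            }
        )
        p_csv = out / "atten" / "global_fits.csv"
        p_csv.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p_csv, index=False)
        paths = [
            write_float_tiff(out / "atten" / "mu_local_enface.tiff", en),
            p_csv,
        ]
        record("attenuation", paths)
        return inten, mu_local

    inten_rc, mu_local = run_stage("attenuation", _atten)

    # --- stats --------------------------------------------------------
    if config.stats:
        def _stats():
            nx, ny, _ = inten_rc.shape
            half = nx // 2
            slab = config.enface_slab_um
            regions = [
                RegionSpec("left", (0, half), (0, ny), slab),
                RegionSpec("right", (half, nx), (0, ny), slab),
            ]
            sets = [
                extract_region(inten_rc, surface, r, tom.axial_pitch_um,
                               seed=config.seed + i)
                for i, r in enumerate(regions)
            ]
            table = compare_groups(sets, log_scale=True)
            p_csv = out / "stats" / "pairwise_tests.csv"
            p_csv.parent.mkdir(parents=True, exist_ok=True)
            table.to_csv(p_csv, index=False)
            record("stats", [p_csv])

        run_stage("stats", _stats)

    manifest = RunManifest(
        config_hash=config.config_hash(), stages=stages, timestamp=time.time()
    )
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
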