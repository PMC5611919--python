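"""Region sampling and group statistics for tissue discrimination.

Samples voxel values (intensity or local attenuation) from labelled,
surface-referenced regions, pairs intensity with attenuation for cluster
summaries, runs Bonferroni-corrected pairwise two-sample t-tests, and
tracks signal amplitude through an optical-clearing time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .reconstruct import SurfaceMap, slab_pixel_range


@dataclass(frozen=True)
class RegionSpec:
    """A lateral rectangle with a surface-referenced depth slab."""

    label: str
    x_range: tuple  # half-open index range
    y_range: tuple
    depth_um: tuple  # (start, end) below the surface
    sample_count: int = 200

    def __post_init__(self):
        if self.sample_count < 1:
            raise ValueError("sample_count must be >= 1")
        if self.depth_um[1] <= self.depth_um[0]:
            raise ValueError("depth slab must have positive extent")


@dataclass
class SampleSet:
    values: np.ndarray
    label: str
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample values must be finite")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TimecoursePoint:
    time_min: float
    mean_amplitude: float
    sd: float


def region_voxel_values(
    volume: np.ndarray, surface: SurfaceMap, region: RegionSpec, axial_pitch_um: float
) -> np.ndarray:
    """All finite voxel values inside a surface-referenced region."""
    nx, ny, nz = volume.shape
    x0, x1 = region.x_range
    y0, y1 = region.y_range
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise ValueError("region bounds exceed the volume")
    vals = []
    for ix in range(x0, x1):
        for iy in range(y0, y1):
            if not surface.valid_mask[ix, iy]:
                continue
            lo, hi, _ = slab_pixel_range(
                int(surface.surface_index[ix, iy]),
                region.depth_um[0],
                region.depth_um[1],
                axial_pitch_um,
                nz,
            )
            if hi > lo:
                vals.append(volume[ix, iy, lo:hi])
    if not vals:
        return np.zeros(0)
    out = np.concatenate(vals).astype(float)
    return out[np.isfinite(out)]


def extract_region(
    volume: np.ndarray,
    surface: SurfaceMap,
    region: RegionSpec,
    axial_pitch_um: float,
    seed: int = 0,
    units: str = "",
) -> SampleSet:
    """Draw a seeded subsample of voxel values from a region.

    If the region holds no more voxels than ``sample_count`` every voxel
    is returned once; otherwise a uniform subsample without replacement
    is drawn deterministically from ``seed``.
    """
    vals = region_voxel_values(volume, surface, region, axial_pitch_um)
    if vals.size == 0:
        raise ValueError(f"region {region.label!r} contains no valid voxels")
    if vals.size > region.sample_count:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(vals.size, size=region.sample_count, replace=False))
        vals = vals[idx]
    return SampleSet(values=vals, label=region.label, units=units)


def pair_intensity_attenuation(intensity, attenuation):
    """Index-aligned (intensity, attenuation) pairs with group centroids.

    Accepts a single SampleSet per quantity or equal-length lists of them
    (one per group).  Returns a dict with the paired DataFrame, per-group
    centroids and, for >= 2 groups, pairwise centroid separation in units
    of the pooled per-axis standard deviation.
    """
    ints = intensity if isinstance(intensity, (list, tuple)) else [intensity]
    atts = attenuation if isinstance(attenuation, (list, tuple)) else [attenuation]
    if len(ints) != len(atts):
        raise ValueError("need one attenuation set per intensity set")
    frames = []
    for i_set, a_set in zip(ints, atts):
        if i_set.n != a_set.n:
            raise ValueError(
                f"group {i_set.label!r}: {i_set.n} intensity vs {a_set.n} attenuation samples"
            )
        if i_set.label != a_set.label:
            raise ValueError("paired sets must come from the same region")
        frames.append(
            pd.DataFrame(
                {"intensity": i_set.values, "attenuation": a_set.values, "label": i_set.label}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    centroids = data.groupby("label", sort=False)[["intensity", "attenuation"]].mean()

    separations = {}
    labels = list(centroids.index)
    for a, b in combinations(labels, 2):
        da = data[data.label == a][["intensity", "attenuation"]].to_numpy()
        db = data[data.label == b][["intensity", "attenuation"]].to_numpy()
        pooled_var = (da.var(axis=0, ddof=1) + db.var(axis=0, ddof=1)) / 2.0
        diff = centroids.loc[a].to_numpy() - centroids.loc[b].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            sep = float(np.sqrt(np.nansum(diff**2 / np.where(pooled_var > 0, pooled_var, np.nan))))
        separations[(a, b)] = sep
    return {"data": data, "centroids": centroids, "separation": separations}


def compare_groups(
    samples,
    alpha: float = 0.05,
    *,
    equal_var: bool = False,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise two-sample t-tests.

    For every unordered pair of groups a Welch (default) or pooled t-test
    is run; the Bonferroni-adjusted p is min(1, m * p) with m the number
    of pairs, and a pair is significant iff the adjusted p < ``alpha``.
    With ``log_scale`` the comparison is on 10*log10 of the values (dB).
    """
    if len(samples) < 2:
        raise ValueError("at least two groups are required")
    for s in samples:
        if s.n < 2:
            raise ValueError(f"group {s.label!r} needs n >= 2")
    m = len(samples) * (len(samples) - 1) // 2
    rows = []
    for a, b in combinations(samples, 2):
        va, vb = a.values, b.values
        if log_scale:
            if np.any(va <= 0) or np.any(vb <= 0):
                raise ValueError("log-scale comparison requires positive values")
            va, vb = 10 * np.log10(va), 10 * np.log10(vb)
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            # degenerate: identical constants are indistinguishable,
            # different constants are trivially separated
            if va.mean() == vb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.inf, 0.0
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
        p_adj = min(1.0, m * float(p))
        rows.append(
            {
                "group_a": a.label,
                "group_b": b.label,
                "n_a": a.n,
                "n_b": b.n,
                "t": float(t),
                "p_raw": float(p),
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def clearing_timecourse(
    volumes,
    surfaces,
    roi: RegionSpec,
    axial_pitch_um: float,
    times_min,
):
    """Normalised amplitude time course through an optical-clearing series.

    Per time point the mean and SD of the (amplitude) voxel values in the
    surface-referenced ROI are computed, then every value is divided by
    the mean of the first (pre-clearing) time point.  Returns the points
    and the least-squares linear trend through the normalised means.
    Time points whose ROI has no valid surface are dropped with a warning.
    """
    times = list(times_min)
    if len(volumes) < 2 or len(volumes) != len(surfaces) or len(volumes) != len(times):
        raise ValueError("need >= 2 aligned (volume, surface, time) triples")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    raw = []
    for vol, surf, t in zip(volumes, surfaces, times):
        vals = region_voxel_values(vol, surf, roi, axial_pitch_um)
        if vals.size == 0:
            warnings.warn(f"no valid surface in ROI at t={t} min; point dropped")
            continue
        raw.append((t, vals.mean(), vals.std(ddof=1) if vals.size > 1 else 0.0))
    if len(raw) < 2:
        raise ValueError("fewer than two usable time points")
    ref = raw[0][1]
    points = [TimecoursePoint(t, m / ref, s / ref) for t, m, s in raw]
    tt = np.array([p.time_min for p in points])
    mm = np.array([p.mean_amplitude for p in points])
    slope, intercept = np.polyfit(tt, mm, 1)
    return points, {"slope_per_min": float(slope), "intercept": float(intercept)}
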