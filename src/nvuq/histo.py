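"""Histology-side estimators.

Three independent quantities:

* **Plaque volumetric density** — plaques counted in a Z-stack divided by the
  tissue volume enclosed between an interpolated brain-surface model (built
  from 50-200 manually labelled surface points) and the stack bottom.
* **Perivascular fibrinogen profiles** — a band from 3 um inside to 11 um
  outside a traced vessel boundary is straightened into an (L, x) rectangle,
  cresyl-violet nuclei are masked out, and the band is averaged along L; per
  animal the per-vessel profiles are averaged weighted by traced length L and
  normalised so the lumen minimum maps to 0 and the mean of the last 10
  points (far parenchyma) to 1.
* **Pericyte linear density** — capillary-associated pericyte somata per unit
  capillary length (capillaries only, diameter < 10 um), pooled per animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

__all__ = ["SurfaceModel", "PlaqueSet", "VesselProfile", "PericyteCount",
           "brain_volume", "plaque_density", "detect_plaques",
           "straighten_profile", "aggregate_profiles", "fit_enrichment_decay",
           "pericyte_density"]


class SurfaceModel:
    """Piecewise-linear brain surface z_s(x, y) from labelled points (um).

    Linear interpolation over a Delaunay triangulation of the labelled points,
    extended by nearest-point values outside the convex hull so the surface is
    defined over the full field.
    """

    def __init__(self, points_um: np.ndarray):
        pts = np.asarray(points_um, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
            raise ValueError("need >= 3 surface points as (x, y, z) um rows")
        xy, z = pts[:, :2], pts[:, 2]
        if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
            raise ValueError("surface points are collinear")
        self.points = pts
        self._lin = LinearNDInterpolator(xy, z)
        self._near = NearestNDInterpolator(xy, z)

    def z_at(self, x, y) -> np.ndarray:
        z = self._lin(x, y)
        out = np.asarray(z, dtype=float)
        bad = np.isnan(out)
        if np.any(bad):
            nearest = np.asarray(self._near(x, y), dtype=float)
            out = np.where(bad, nearest, out)
        return out if out.ndim else float(out)


@dataclass
class PlaqueSet:
    """Manually (or synthetically) placed plaque centers, (x, y, z) um."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)

    @property
    def count(self) -> int:
        return len(self.centers)


def brain_volume(field_um: tuple[float, float], z_bottom_um: float,
                 surface: SurfaceModel, grid_step_um: float = 1.0) -> float:
    """Tissue volume (mm^3) between the surface model and the stack bottom.

    Integrated column-wise on a regular grid: per (x, y) column the depth is
    ``max(0, z_bottom - clip(z_s, 0, z_bottom))`` (surface above the stack top
    contributes the full stack depth).
    """
    sx, sy = field_um
    xs = np.arange(grid_step_um / 2, sx, grid_step_um)
    ys = np.arange(grid_step_um / 2, sy, grid_step_um)
    xx, yy = np.meshgrid(xs, ys)
    zs = np.asarray(surface.z_at(xx.ravel(), yy.ravel())).reshape(xx.shape)
    depth = z_bottom_um - np.clip(zs, 0.0, z_bottom_um)
    vol_um3 = float(depth.sum()) * grid_step_um**2
    return vol_um3 * 1e-9


def plaque_density(plaques: PlaqueSet, volume_mm3: float) -> float:
    """Plaques per mm^3."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    return plaques.count / volume_mm3


def detect_plaques(autofluorescence: np.ndarray, geometry, min_intensity: float,
                   sigma_um: float = 5.0) -> PlaqueSet:
    """Blob detection of autofluorescent plaques in a (Z, Y, X) volume.

    A Laplacian-of-Gaussian-free shortcut suited to the synthetic blobs:
    smooth at the expected plaque scale, find local maxima above threshold.
    Provided for simulated scenes; the density estimator itself accepts
    manual center lists.
    """
    voxel = np.array([geometry.z_step, geometry.pixel_size_xy,
                      geometry.pixel_size_xy])
    sm = ndimage.gaussian_filter(np.asarray(autofluorescence, float),
                                 sigma_um / voxel / 2)
    peaks = (sm == ndimage.maximum_filter(sm, size=3, mode="nearest")) \
        & (sm >= min_intensity)
    zyx = np.argwhere(peaks) * voxel
    return PlaqueSet(zyx[:, ::-1])  # (x, y, z)


@dataclass
class VesselProfile:
    """One wall-side intensity profile across a traced vessel boundary."""

    L_um: float                     # traced vessel length (the weight)
    x_offsets: np.ndarray           # um from the boundary, lumen side negative
    raw_profile: np.ndarray         # a.u.
    normalized_profile: np.ndarray | None = None
    side: str = "right"

    def __post_init__(self) -> None:
        self.x_offsets = np.asarray(self.x_offsets, dtype=float)
        self.raw_profile = np.asarray(self.raw_profile, dtype=float)
        if not np.all(np.diff(self.x_offsets) > 0):
            raise ValueError("x offsets must be increasing")


def fibrinogen_channel(rgb: np.ndarray) -> np.ndarray:
    """Inverted blue channel of an sRGB DAB section, as float."""
    return 255.0 - np.asarray(rgb, dtype=float)[..., 2]


def nuclei_mask_from_red(rgb: np.ndarray, threshold: float = 140.0) -> np.ndarray:
    """Cresyl-violet nuclei absorb strongly in the red channel; mask pixels
    whose red value falls below ``threshold``."""
    return np.asarray(rgb, dtype=float)[..., 0] < threshold


def straighten_profile(
    image: np.ndarray,
    trace_px: np.ndarray,
    nuclei_mask: np.ndarray | None = None,
    *,
    pixel_size_um: float = 0.5,
    x_range_um: tuple[float, float] = (-3.0, 11.0),
    x_step_um: float = 0.5,
    l_step_um: float = 1.0,
    side: str = "right",
) -> VesselProfile:
    """Straighten the band around a vessel-boundary polyline and average it.

    ``image`` is RGB (H, W, 3) — the fibrinogen signal is the inverted blue
    channel — or a prepared 2-D intensity array.  ``trace_px`` is an (n, 2)
    polyline of (x, y) pixel vertices.  The band from ``x_range_um[0]``
    (lumen side) to ``x_range_um[1]`` (parenchyma side), measured normal to
    the trace, is resampled bilinearly onto an (L, x) rectangle; for
    ``side="left"`` the normal is flipped so both walls of a vessel can be
    profiled.  Nucleus-masked pixels are dropped before averaging along L;
    columns left empty are interpolated from their neighbours.
    """
    img = fibrinogen_channel(image) if image.ndim == 3 else np.asarray(image, float)
    trace = np.asarray(trace_px, dtype=float).reshape(-1, 2)
    if len(trace) < 2:
        raise ValueError("trace needs >= 2 vertices")
    if (trace < 0).any() or (trace[:, 0] > img.shape[1] - 1).any() \
            or (trace[:, 1] > img.shape[0] - 1).any():
        raise ValueError("trace exits image bounds")

    # arclength parametrisation at l_step (um)
    seg = np.diff(trace, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1]) * pixel_size_um
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    L = float(s[-1])
    if L <= 0:
        raise ValueError("degenerate trace")
    samples_l = np.arange(0, L + l_step_um / 2, l_step_um)
    px = np.interp(samples_l, s, trace[:, 0])
    py = np.interp(samples_l, s, trace[:, 1])
    # unit tangents then normals (right-hand normal; flipped for side="left")
    tx = np.gradient(px)
    ty = np.gradient(py)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx_, ny_ = -ty / norm, tx / norm
    if side == "left":
        nx_, ny_ = -nx_, -ny_

    x_off = np.arange(x_range_um[0], x_range_um[1] + x_step_um / 2, x_step_um)
    xs = px[:, None] + nx_[:, None] * (x_off[None, :] / pixel_size_um)
    ys = py[:, None] + ny_[:, None] * (x_off[None, :] / pixel_size_um)
    if xs.min() < -0.5 or ys.min() < -0.5 or xs.max() > img.shape[1] - 0.5 \
            or ys.max() > img.shape[0] - 0.5:
        raise ValueError("sampling band exits image bounds")
    band = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1,
                                   mode="nearest").reshape(xs.shape)
    if nuclei_mask is not None:
        excl = ndimage.map_coordinates(nuclei_mask.astype(float),
                                       [ys.ravel(), xs.ravel()], order=0,
                                       mode="nearest").reshape(xs.shape) > 0.5
        band = np.where(excl, np.nan, band)

    with np.errstate(invalid="ignore"):
        prof = np.nanmean(band, axis=0)
    empty = np.isnan(prof)
    if empty.all():
        raise ValueError("entire band nucleus-masked")
    if empty.any():
        prof[empty] = np.interp(x_off[empty], x_off[~empty], prof[~empty])
    return VesselProfile(L, x_off, prof, side=side)


def aggregate_profiles(profiles: list[VesselProfile], n_background: int = 10
                       ) -> VesselProfile:
    """Length-weighted mean profile, normalised to [lumen 0, background 1].

    Weights are the traced lengths L; the normalisation maps the profile
    minimum to 0 and the mean of the last ``n_background`` points to 1, so
    perivascular enrichment shows up as values above 1 near the wall.
    """
    if not profiles:
        raise ValueError("no profiles")
    x0 = profiles[0].x_offsets
    for p in profiles:
        if not np.array_equal(p.x_offsets, x0):
            raise ValueError("profiles must share a common x grid")
    w = np.array([p.L_um for p in profiles], dtype=float)
    raw = np.array([p.raw_profile for p in profiles])
    mean = (w[:, None] * raw).sum(axis=0) / w.sum()
    lo = float(mean.min())
    bg = float(mean[-n_background:].mean())
    if bg == lo:
        raise ValueError("flat profile: normalisation undefined")
    normed = (mean - lo) / (bg - lo)
    return VesselProfile(float(w.sum()), x0, mean, normed, side="mean")


def fit_enrichment_decay(profile: VesselProfile, x_min_um: float = 0.5,
                         n_background: int = 10) -> tuple[float, float]:
    """Fit ``A * exp(-x/lambda)`` to the above-background tail beyond the wall.

    Returns ``(A, lambda_um)`` on the normalised profile (background = 1).
    """
    if profile.normalized_profile is None:
        raise ValueError("aggregate the profile first")
    x = profile.x_offsets
    y = profile.normalized_profile - 1.0
    sel = x >= x_min_um
    popt, _ = optimize.curve_fit(
        lambda xx, a, lam: a * np.exp(-xx / lam), x[sel], y[sel],
        p0=(max(y[sel].max(), 1e-3), 3.0), maxfev=10000)
    return float(popt[0]), float(popt[1])


@dataclass(frozen=True)
class PericyteCount:
    stack_id: str
    n_pericytes: int
    total_capillary_length_um: float
    mouse_id: str = ""

    def __post_init__(self) -> None:
        if self.n_pericytes < 0 or self.total_capillary_length_um < 0:
            raise ValueError("counts and lengths must be non-negative")


def pericyte_density(counts: list[PericyteCount]) -> float:
    """Pooled pericytes per mm of capillary: sum(n) / sum(L)."""
    total_l = sum(c.total_capillary_length_um for c in counts)
    if total_l <= 0:
        raise ValueError("zero total capillary length")
    total_n = sum(c.n_pericytes for c in counts)
    return total_n / (total_l / 1000.0)
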