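"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and an integer seed
(PCG64 via :func:`numpy.random.default_rng`), so downstream estimators can be
validated by parameter recovery without any external data.

What is emulated, and what is not: vessels are straight tubes (no branching
topology), punctae are a Poisson point process on the vessel wall, plaques a
3-D Poisson process in parenchyma, detector noise is additive Gaussian, and
drift is rigid lateral translation.  Scattering, depth attenuation and motion
beyond rigid drift are deliberately absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .io import HyperStack, VoxelGeometry

#: the seven vessel types scored for transcytosis
VESSEL_TYPES = (
    "pial arteriole",
    "penetrating arteriole (pial)",
    "penetrating arteriole (parenchymal)",
    "capillary",
    "ascending venule (parenchymal)",
    "ascending venule (pial)",
    "pial venule",
)

#: typical lumen diameters (um) used when laying out a synthetic scene
DEFAULT_DIAMETERS = {
    "pial arteriole": 25.0,
    "penetrating arteriole (pial)": 15.0,
    "penetrating arteriole (parenchymal)": 12.0,
    "capillary": 6.0,
    "ascending venule (parenchymal)": 9.0,
    "ascending venule (pial)": 15.0,
    "pial venule": 30.0,
}

#: default wall punctae densities (punctae per um^2 of lateral surface);
#: arterioles carry more transcytotic punctae than capillaries and venules
DEFAULT_DENSITIES = {
    "pial arteriole": 0.010,
    "penetrating arteriole (pial)": 0.008,
    "penetrating arteriole (parenchymal)": 0.008,
    "capillary": 0.003,
    "ascending venule (parenchymal)": 0.003,
    "ascending venule (pial)": 0.003,
    "pial venule": 0.003,
}

PUNCTA_FWHM_UM = 0.6  # diffraction-limited vesicle spot size


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSegment:
    segment_id: str
    vessel_type: str
    length_um: float
    diameter_um: float
    n_punctae: int
    axis_x_um: float          # tube axis position (tube runs along Y)
    axis_z_um: float
    wall_points_um: np.ndarray  # (n, 3) puncta positions as (x, y, z) um


@dataclass
class SceneTruth:
    """Ground truth for one generated transcytosis scene."""

    seed: int
    segments: list[SyntheticSegment]
    true_density_by_type: dict[str, float]
    plaque_centers: np.ndarray          # (n, 3) um, (x, y, z)
    true_plaque_density: float          # plaques per mm^3
    size_um: tuple[float, float, float]
    vessel_mask: np.ndarray | None = None   # (Z, Y, X) bool
    punctae_mask: np.ndarray | None = None
    plaque_mask: np.ndarray | None = None


@dataclass
class LeakageTruth:
    """Closed-form truth for a tracer-leakage time-lapse.

    Blood follows ``C_b(t) = c0 exp(-t/tau)``; parenchyma integrates the
    uptake ``dC_p/dt = k C_b`` giving ``C_p(t) = k c0 tau (1 - exp(-t/tau))``.
    Over a recording of length T the continuous AUC ratio is

        ratio = k * tau * [T - tau(1 - e^{-T/tau})] / [tau(1 - e^{-T/tau})]
    """

    k_perm: float       # 1/min
    tau_blood: float    # min
    c0: float           # a.u.
    duration_min: float
    step_min: float
    expected_ratio: float
    blood_mask: np.ndarray | None = None    # (Y, X) bool, pial vessel at plane 0
    shadow_mask: np.ndarray | None = None   # (Y, X) bool, under-vessel exclusion
    plaque_mask: np.ndarray | None = None   # (Y, X) bool, under-plaque exclusion


def leakage_expected_ratio(k_perm: float, tau_blood: float, duration_min: float) -> float:
    """Continuous-time AUC(parenchyma)/AUC(blood) of the uptake model."""
    if tau_blood <= 0 or duration_min <= 0:
        raise ValueError("tau_blood and duration must be positive")
    a = tau_blood * (1.0 - math.exp(-duration_min / tau_blood))  # AUC of e^{-t/tau}
    return k_perm * tau_blood * (duration_min - a) / a


@dataclass
class NvcTruth:
    """Programmed diameter dynamics of a stimulus-locked vessel movie."""

    d0_true: float            # um
    dilation_frac: float      # (Dp - D0)/D0
    onset_s: float = 40.0
    stim_dur_s: float = 15.0
    post_s: float = 75.0
    plateau_len: int = 8      # frames held at peak; >= 5 so window-5 smoothing keeps it
    rise_s: float = 3.0
    relax_s: float = 20.0

    def __post_init__(self) -> None:
        if self.dilation_frac < -1:
            raise ValueError("dilation_frac must be >= -1")
        if self.plateau_len < 5:
            raise ValueError("plateau_len must be >= 5 frames")

    def diameter_at(self, t: np.ndarray, time_step: float) -> np.ndarray:
        """True diameter (um) at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        peak = self.d0_true * (1.0 + self.dilation_frac)
        plateau_s = self.plateau_len * time_step
        t1 = self.onset_s + self.rise_s
        t2 = t1 + plateau_s
        t3 = t2 + self.relax_s
        d = np.full_like(t, self.d0_true)
        rising = (t >= self.onset_s) & (t < t1)
        d[rising] = self.d0_true + (peak - self.d0_true) * (t[rising] - self.onset_s) / self.rise_s
        d[(t >= t1) & (t < t2)] = peak
        relaxing = (t >= t2) & (t < t3)
        d[relaxing] = peak + (self.d0_true - peak) * (t[relaxing] - t2) / self.relax_s
        return d


@dataclass
class SectionTruth:
    """Ground truth for a synthetic DAB-stained histology section.

    The fibrinogen signal lives in the *inverted* blue channel: ``lumen_level``
    inside the vessel, ``background_level`` far into parenchyma, plus an
    exponential perivascular enrichment ``enrich_amp * exp(-x/enrich_decay)``
    beyond the wall.  Cresyl-violet nuclei contaminate the blue channel and
    are rendered into the red channel so a nucleus mask can be thresholded.
    """

    wall_x_um: float = 60.0       # boundary offset from the image left edge
    angle_deg: float = 0.0        # trace orientation (0 = vertical boundary)
    enrich_amp: float = 0.0
    enrich_decay: float = 3.0     # um
    lumen_level: float = 10.0
    background_level: float = 100.0
    n_nuclei: int = 0
    nucleus_radius_um: float = 3.0
    nucleus_blue_dip: float = 60.0
    pixel_size_um: float = 0.5
    nuclei_centers: np.ndarray | None = None  # (n, 2) as (x, y) px, filled by generator

    def __post_init__(self) -> None:
        if self.enrich_decay <= 0:
            raise ValueError("enrich_decay must be positive")
        if self.background_level <= self.lumen_level:
            raise ValueError("background_level must exceed lumen_level")


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _stamp_gaussian(vol: np.ndarray, center_vox: np.ndarray, sigma_vox: np.ndarray,
                    amplitude: float) -> None:
    """Add a 3-D Gaussian spot to ``vol`` (Z, Y, X) over a local window."""
    lo = np.maximum(0, np.floor(center_vox - 4 * sigma_vox).astype(int))
    hi = np.minimum(vol.shape, np.ceil(center_vox + 4 * sigma_vox).astype(int) + 1)
    if np.any(lo >= hi):
        return
    grids = np.ix_(*(np.arange(l, h) for l, h in zip(lo, hi)))
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center_vox, sigma_vox))
    vol[grids[0], grids[1], grids[2]] += amplitude * np.exp(-0.5 * r2)


def tube_profile(y_um: np.ndarray, center_um: float, diameter_um: float,
                 psf_sigma_um: float = 0.5) -> np.ndarray:
    """Cross profile of a dye-filled tube: a top-hat of width ``diameter_um``
    blurred by a Gaussian PSF, so the full width at half maximum equals the
    true diameter (for diameters well above the PSF width)."""
    r = diameter_um / 2.0
    s = psf_sigma_um * math.sqrt(2.0)
    return 0.5 * (special.erf((y_um - center_um + r) / s)
                  - special.erf((y_um - center_um - r) / s))


# ---------------------------------------------------------------------------
# transcytosis scene
# ---------------------------------------------------------------------------

def generate_amt_scene(
    geometry: VoxelGeometry,
    density_by_type: dict[str, float] | None = None,
    plaque_density: float = 2200.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    *,
    size_um: tuple[float, float, float] = (250.0, 250.0, 150.0),
    vessel_amp: float = 100.0,
    puncta_amp: float = 150.0,
    plaque_amp: float = 80.0,
    render: bool = True,
) -> tuple[HyperStack | None, SceneTruth]:
    """Generate a two-channel transcytosis Z-stack with known ground truth.

    Straight tubes, one per vessel type that fits the field laterally, run the
    full Y extent; punctae are a Poisson process on each tube's lateral
    surface ``a = pi * d * l`` at the per-type density; plaques are a 3-D
    Poisson process in the volume at ``plaque_density`` per mm^3, rendered
    into the autofluorescence channel.  With ``render=False`` only the truth
    record is built (no voxel data), which is cheap enough for count-level
    simulation studies.
    """
    if density_by_type is None:
        density_by_type = dict(DEFAULT_DENSITIES)
    if any(v < 0 for v in density_by_type.values()) or plaque_density < 0:
        raise ValueError("densities must be non-negative")
    sx, sy, sz = size_um
    rng = np.random.default_rng(seed)

    # lateral layout: tubes along Y, spread across X at depth-appropriate Z
    types = sorted((t for t in VESSEL_TYPES if t in density_by_type),
                   key=lambda t: DEFAULT_DIAMETERS[t])
    # greedy lateral packing: as many of the vessel types as fit the field,
    # smallest first, each in a slot 1.5 diameters wide
    segments: list[SyntheticSegment] = []
    cursor = 0.0
    placed: list[tuple[str, float]] = []
    for typ in types:
        d = DEFAULT_DIAMETERS[typ]
        if cursor + 1.5 * d <= sx and d / 2 <= sz:
            placed.append((typ, cursor + 0.75 * d))
            cursor += 1.5 * d
    if not placed:
        raise ValueError(f"field {size_um} um too small to contain any vessel")
    for i, (typ, x0) in enumerate(placed):
        d = DEFAULT_DIAMETERS[typ]
        z0 = min(d, sz / 4) if "pial" in typ else sz / 2
        length = sy
        area = math.pi * d * length
        n = int(rng.poisson(density_by_type[typ] * area))
        ypos = rng.uniform(0, length, n)
        theta = rng.uniform(0, 2 * math.pi, n)
        pts = np.column_stack([x0 + (d / 2) * np.cos(theta), ypos,
                               z0 + (d / 2) * np.sin(theta)])
        segments.append(SyntheticSegment(f"seg{i}", typ, length, d, n, x0, z0, pts))

    vol_mm3 = sx * sy * sz * 1e-9
    n_plaques = int(rng.poisson(plaque_density * vol_mm3))
    plaque_centers = rng.uniform([0, 0, 0], [sx, sy, sz], (n_plaques, 3))

    truth = SceneTruth(seed, segments, dict(density_by_type), plaque_centers,
                       plaque_density, size_um)
    if not render:
        return None, truth

    nx = max(1, round(sx / geometry.pixel_size_xy))
    ny = max(1, round(sy / geometry.pixel_size_xy))
    nz = max(1, round(sz / geometry.z_step))
    xs = (np.arange(nx) + 0.5) * geometry.pixel_size_xy
    zs = (np.arange(nz) + 0.5) * geometry.z_step

    # vessels: Gaussian radial fall-off sigma = d/4 in the XZ plane,
    # constant along the tube (Y)
    xz = np.zeros((nz, nx))
    vmask_xz = np.zeros((nz, nx), dtype=bool)
    for seg in segments:
        r2 = ((xs[None, :] - seg.axis_x_um) ** 2 + (zs[:, None] - seg.axis_z_um) ** 2)
        sigma = seg.diameter_um / 4.0
        xz += vessel_amp * np.exp(-0.5 * r2 / sigma**2)
        vmask_xz |= r2 <= (seg.diameter_um / 2.0) ** 2
    tracer = np.broadcast_to(xz[:, None, :], (nz, ny, nx)).copy()
    vessel_mask = np.broadcast_to(vmask_xz[:, None, :], (nz, ny, nx)).copy()

    voxel = np.array([geometry.z_step, geometry.pixel_size_xy, geometry.pixel_size_xy])
    psigma_um = PUNCTA_FWHM_UM / 2.3548
    punctae_mask = np.zeros_like(vessel_mask)
    for seg in segments:
        for x, y, z in seg.wall_points_um:
            c = np.array([z, y, x]) / voxel
            _stamp_gaussian(tracer, c, np.maximum(psigma_um / voxel, 0.35), puncta_amp)
            iz, iy, ix = np.clip(np.rint(c).astype(int), 0, np.array(tracer.shape) - 1)
            punctae_mask[iz, iy, ix] = True

    autofl = np.zeros_like(tracer)
    plaque_mask = np.zeros_like(vessel_mask)
    plaque_sigma_um = 5.0
    for x, y, z in plaque_centers:
        c = np.array([z, y, x]) / voxel
        _stamp_gaussian(autofl, c, plaque_sigma_um / voxel, plaque_amp)
        lo = np.maximum(0, np.floor(c - plaque_sigma_um / voxel).astype(int))
        hi = np.minimum(plaque_mask.shape, np.ceil(c + plaque_sigma_um / voxel).astype(int) + 1)
        plaque_mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True

    data = np.stack([tracer, autofl], axis=1)[None]  # (T=1, Z, C, Y, X)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    stack = HyperStack(data, geometry, ["tracer", "autofluorescence"])
    truth.vessel_mask = vessel_mask
    truth.punctae_mask = punctae_mask
    truth.plaque_mask = plaque_mask
    return stack, truth


# ---------------------------------------------------------------------------
# paracellular-leakage time-lapse
# ---------------------------------------------------------------------------

def generate_leakage_timelapse(
    k_perm: float,
    tau_blood: float = 20.0,
    c0: float = 1000.0,
    duration_min: float = 45.0,
    step_min: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    geometry: VoxelGeometry | None = None,
    size_um: tuple[float, float] = (128.0, 128.0),
    depth_um: float = 100.0,
    with_obstacles: bool = True,
) -> tuple[HyperStack, LeakageTruth]:
    """Generate a tracer-injection time-lapse following the uptake model.

    Blood voxels (a pial-vessel strip at plane 0) decay as ``c0 e^{-t/tau}``;
    parenchyma rises as ``k c0 tau (1 - e^{-t/tau})``.  Frames are recorded
    every ``step_min`` from 0 to ``duration_min`` inclusive.  When
    ``with_obstacles`` is set, a vessel-shadow strip and a plaque disc are
    flagged in the truth (and attenuated in the rendered frames) so ROI
    placement constraints can be exercised.
    """
    if tau_blood <= 0 or duration_min <= 0 or step_min <= 0:
        raise ValueError("tau_blood, duration and step must be positive")
    if geometry is None:
        geometry = VoxelGeometry(pixel_size_xy=1.0, z_step=20.0,
                                 time_step=step_min * 60.0)
    rng = np.random.default_rng(seed)
    sx, sy = size_um
    nx = max(1, round(sx / geometry.pixel_size_xy))
    ny = max(1, round(sy / geometry.pixel_size_xy))
    nz = int(round(depth_um / geometry.z_step)) + 1
    t = np.arange(0.0, duration_min + step_min / 2, step_min)

    blood_mask = np.zeros((ny, nx), dtype=bool)
    blood_mask[:, : max(2, nx // 8)] = True  # pial vessel along the left edge
    shadow_mask = np.zeros_like(blood_mask)
    plaque_mask = np.zeros_like(blood_mask)
    if with_obstacles:
        w = max(2, nx // 10)
        shadow_mask[:, nx // 2: nx // 2 + w] = True
        yy, xx = np.mgrid[0:ny, 0:nx]
        plaque_mask[(yy - ny // 4) ** 2 + (xx - 3 * nx // 4) ** 2 < (nx // 12) ** 2] = True

    cb = c0 * np.exp(-t / tau_blood)                       # (T,)
    cp = k_perm * c0 * tau_blood * (1.0 - np.exp(-t / tau_blood))
    frame = np.where(blood_mask, 1.0, 0.0)                 # (Y, X)
    atten = np.where(shadow_mask | plaque_mask, 0.5, 1.0)
    data = np.empty((len(t), nz, 1, ny, nx))
    for i in range(len(t)):
        plane_par = cp[i] * atten
        for z in range(nz):
            img = plane_par.copy()
            if z == 0:
                img = np.where(blood_mask, cb[i], img)
            data[i, z, 0] = img
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    stack = HyperStack(data, geometry)
    truth = LeakageTruth(k_perm, tau_blood, c0, duration_min, step_min,
                         leakage_expected_ratio(k_perm, tau_blood, duration_min),
                         blood_mask, shadow_mask, plaque_mask)
    return stack, truth


# ---------------------------------------------------------------------------
# neurovascular-coupling movie
# ---------------------------------------------------------------------------

def generate_nvc_timelapse(
    truth: NvcTruth,
    geometry: VoxelGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    size_um: tuple[float, float] = (48.0, 32.0),
    n_planes: int = 3,
    amp: float = 100.0,
    psf_sigma_um: float = 0.5,
) -> tuple[HyperStack, NvcTruth]:
    """Render a bright dye-filled tube whose diameter follows ``truth``.

    The tube runs along X at mid-Y (with a random sub-pixel offset so pixel
    quantisation dithers across seeds); its cross profile is a PSF-blurred
    top-hat, so thresholding at half amplitude recovers the true diameter.
    """
    if geometry is None:
        geometry = VoxelGeometry(pixel_size_xy=0.5, z_step=2.5, time_step=1.5)
    rng = np.random.default_rng(seed)
    sx, sy = size_um
    nx = round(sx / geometry.pixel_size_xy)
    ny = round(sy / geometry.pixel_size_xy)
    total_s = truth.onset_s + truth.stim_dur_s + truth.post_s
    nt = int(round(total_s / geometry.time_step)) + 1
    times = np.arange(nt) * geometry.time_step
    diam = truth.diameter_at(times, geometry.time_step)

    yc = sy / 2 + rng.uniform(-0.5, 0.5) * geometry.pixel_size_xy
    y_um = (np.arange(ny) + 0.5) * geometry.pixel_size_xy
    prof = np.stack([amp * tube_profile(y_um, yc, d, psf_sigma_um) for d in diam])
    data = np.broadcast_to(prof[:, None, None, :, None],
                           (nt, n_planes, 1, ny, nx)).copy()
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    return HyperStack(data, geometry), truth


# ---------------------------------------------------------------------------
# histology section
# ---------------------------------------------------------------------------

def generate_fibrinogen_section(
    truth: SectionTruth,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, SectionTruth]:
    """Render an RGB bright-field section with a straight vessel boundary.

    Returns a ``(H, W, 3)`` uint8 image.  The vessel lumen occupies the side
    of the boundary nearer the left edge; the boundary is a straight line at
    ``truth.angle_deg`` from vertical through ``wall_x_um``.
    """
    ny, nx = size
    px = truth.pixel_size_um
    if not (0 < truth.wall_x_um < nx * px):
        raise ValueError("vessel boundary exits image bounds")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    th = math.radians(truth.angle_deg)
    # signed distance (um) from the boundary line, positive into parenchyma
    s = ((xx + 0.5) * px - truth.wall_x_um) * math.cos(th) \
        - ((yy + 0.5) * px - ny * px / 2) * math.sin(th)
    fib = np.where(s < 0, truth.lumen_level,
                   truth.background_level + truth.enrich_amp * np.exp(
                       -np.maximum(s, 0.0) / truth.enrich_decay))
    # mild edge blur emulating optics
    from scipy.ndimage import gaussian_filter
    fib = gaussian_filter(fib, 1.0)

    red = np.full((ny, nx), 200.0)
    centers = []
    for _ in range(truth.n_nuclei):
        cx = rng.uniform(truth.wall_x_um / px + 2, nx - 2)
        cy = rng.uniform(2, ny - 2)
        centers.append((cx, cy))
        r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        # compact-support disc with a 1-px linear edge: the contamination
        # stays inside the red-channel footprint that defines the mask
        blob = np.clip(truth.nucleus_radius_um / px - r, 0.0, 1.0)
        red -= 120.0 * blob                       # cresyl violet absorbs
        fib += truth.nucleus_blue_dip * blob      # contaminates fibrinogen signal
    truth.nuclei_centers = np.array(centers).reshape(-1, 2)

    blue = np.clip(255.0 - fib, 0, 255)
    red = np.clip(red, 0, 255)
    green = np.clip((red + blue) / 2, 0, 255)
    return np.stack([red, green, blue], axis=-1).astype(np.uint8), truth


# ---------------------------------------------------------------------------
# evoked local field potentials
# ---------------------------------------------------------------------------

def generate_lfp_train(
    first_amp_mV: float = 1.2,
    later_amp_mV: float = 1.0,
    n_pulses: int = 30,
    rate_hz: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    sample_rate: float = 20000.0,
    peak_latency_s: float = 0.015,
    pre_s: float = 0.5,
    post_s: float = 0.5,
):
    """Synthesise an evoked LFP train: one negative deflection per pulse.

    Amplitudes are magnitudes in mV (signs are ignored); the first response is
    typically larger due to short-term depression, which is why downstream
    averaging drops it.  Returns an :class:`nvuq.nvc.LfpTrain`.
    """
    from .nvc import LfpTrain
    if n_pulses < 2:
        raise ValueError("n_pulses must be >= 2")
    rng = np.random.default_rng(seed)
    stim_times = pre_s + np.arange(n_pulses) / rate_hz
    n = int(round((pre_s + (n_pulses - 1) / rate_hz + post_s) * sample_rate))
    t = np.arange(n) / sample_rate
    trace = np.zeros(n)
    for i, ts in enumerate(stim_times):
        amp = abs(first_amp_mV) if i == 0 else abs(later_amp_mV)
        u = np.clip(t - ts, 0.0, None)
        resp = (u / peak_latency_s) * np.exp(1 - u / peak_latency_s)
        trace -= amp * resp
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, n)
    return LfpTrain(sample_rate=sample_rate, trace=trace, stimulus_times=stim_times)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    n_per_group: int,
    group_params: dict[str, dict[str, tuple[float, float]]],
    seed: int = 0,
):
    """Draw per-mouse true parameters from lognormal between-mouse variation.

    ``group_params`` maps group name -> measure name -> (mean, CV).  Positive
    physiological quantities vary lognormally between animals; CV = 0 gives
    identical mice.  Returns an :class:`nvuq.io.AnnotationTable` with schema
    ``cohort_truth`` (one row per mouse per measure).  Per-mouse seeds for any
    downstream dataset generation should be derived from the row index and the
    cohort seed.
    """
    import pandas as pd
    from .io import AnnotationTable
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(group_params):
        for i in range(n_per_group):
            mouse = f"{group}-{i:02d}"
            for measure, (mean, cv) in sorted(group_params[group].items()):
                if cv < 0:
                    raise ValueError("CV must be non-negative")
                if mean <= 0:
                    raise ValueError("lognormal mean must be positive")
                if cv == 0:
                    val = mean
                else:
                    s2 = math.log(1.0 + cv * cv)
                    val = rng.lognormal(math.log(mean) - s2 / 2, math.sqrt(s2))
                rows.append({"mouse_id": mouse, "group": group,
                             "measure": measure, "true_value": val})
    return AnnotationTable("cohort_truth", pd.DataFrame(rows))
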