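"""Neurovascular coupling: diameter trajectories and evoked LFP amplitudes.

A stimulus-locked movie (40 s baseline, 15 s whisker-pad stimulation, 75 s
post-stimulation by default) is maximum-projected along Z; a rectangular ROI
across the vessel is collapsed along the vessel's longitude into one cross
profile per frame; the profile is thresholded at a fixed fraction of its
amplitude (a full-width-at-half-maximum analogue at the 0.5 default, constant
over time) and the diameter is the largest above-threshold run times the
pixel size.  From the trajectory:

    D0  = mean diameter over all pre-onset frames
    Dp  = max of the 5-point running average within [onset, onset + 40 s]
    relative dilation = (Dp - D0) / D0

Trajectories with an unstable baseline or pre-onset spontaneous dilation are
excluded.  Evoked LFP amplitude is the mean negative-peak magnitude over all
pulses but the first (the first response is inflated by short-term dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import HyperStack, max_project

__all__ = ["StimulusWindow", "DiameterTrajectory", "NvcResult", "LfpTrain",
           "extract_diameter_trajectory", "baseline_diameter", "running_average",
           "peak_dilation", "qc_exclude", "lfp_amplitude"]


@dataclass(frozen=True)
class StimulusWindow:
    baseline_s: float = 40.0
    stim_s: float = 15.0
    post_s: float = 75.0
    onset_index: int = 0

    def __post_init__(self) -> None:
        if self.onset_index < 1:
            raise ValueError("stimulus onset must follow at least one baseline frame")


VESSEL_CLASSES = ("penetrating arteriole", "precapillary sphincter",
                  "1st-order capillary", "2nd-order capillary")


@dataclass
class DiameterTrajectory:
    times: np.ndarray       # s
    diameters: np.ndarray   # um
    window: StimulusWindow
    vessel_class: str = "penetrating arteriole"
    threshold_used: float = 0.5
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if np.any(self.diameters < 0):
            raise ValueError("diameters must be non-negative")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class NvcResult:
    d0: float
    dp: float
    rel_dilation: float
    excluded: bool = False
    reason: str = ""
    vessel_class: str = ""


@dataclass
class LfpTrain:
    """An evoked LFP recording: voltage trace plus stimulus timestamps."""

    sample_rate: float              # Hz
    trace: np.ndarray               # mV
    stimulus_times: np.ndarray      # s
    amplitudes: np.ndarray | None = None  # filled by lfp_amplitude

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        dur = len(self.trace) / self.sample_rate
        if np.any(self.stimulus_times < 0) or np.any(self.stimulus_times > dur):
            raise ValueError("stimulus times outside the trace")


def extract_diameter_trajectory(
    movie: HyperStack,
    roi: tuple[int, int, int, int],
    threshold_frac: float = 0.5,
    *,
    window: StimulusWindow | None = None,
    longitude_axis: str = "x",
    channel: int = 0,
    vessel_class: str = "penetrating arteriole",
    max_empty_frac: float = 0.2,
) -> DiameterTrajectory:
    """Diameter versus time from a rectangular ROI across a vessel.

    ``roi`` is a half-open pixel box ``(x0, y0, x1, y1)`` whose long axis runs
    along the vessel (``longitude_axis``); the cross profile is the mean along
    that axis.  The threshold is ``min + threshold_frac * (max - min)`` of the
    time-averaged profile, applied unchanged to every frame; the diameter is
    the single largest connected run of above-threshold pixels times the
    pixel size (isolated noise pixels do not count).
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    proj = max_project(movie)
    data = proj.data[:, 0, channel]           # (T, Y, X)
    x0, y0, x1, y1 = roi
    if not (0 <= x0 < x1 <= data.shape[2] and 0 <= y0 < y1 <= data.shape[1]):
        raise ValueError(f"ROI {roi} outside image bounds")
    sub = data[:, y0:y1, x0:x1]
    axis = 2 if longitude_axis == "x" else 1
    profiles = sub.mean(axis=axis)            # (T, cross)
    g = movie.geometry
    times = movie.times()
    win = window or StimulusWindow(onset_index=int(round(40.0 / g.time_step)))

    mean_prof = profiles.mean(axis=0)
    lo, hi = float(mean_prof.min()), float(mean_prof.max())
    flags: list[str] = []
    if hi - lo <= 1e-9 * max(abs(hi), 1.0):
        flags.append("no_vessel")
        return DiameterTrajectory(times, np.zeros(len(times)), win, vessel_class,
                                  threshold_frac, flags)
    thr = lo + threshold_frac * (hi - lo)

    diams = np.empty(len(times))
    n_empty = 0
    for t in range(len(times)):
        fg = profiles[t] >= thr
        if not fg.any():
            n_empty += 1
            diams[t] = 0.0
            continue
        # largest connected run of above-threshold pixels
        padded = np.concatenate([[0], fg.astype(int), [0]])
        edges = np.flatnonzero(np.diff(padded))
        runs = edges[1::2] - edges[0::2]
        diams[t] = runs.max() * g.pixel_size_xy
    if n_empty / len(times) >= max_empty_frac:
        raise ValueError(f"threshold leaves {n_empty}/{len(times)} frames empty")
    if n_empty:
        flags.append("empty_frames")
    return DiameterTrajectory(times, diams, win, vessel_class, threshold_frac, flags)


def baseline_diameter(traj: DiameterTrajectory, min_frames: int = 5) -> float:
    """D0: arithmetic mean of all pre-onset diameters."""
    k = traj.window.onset_index
    if k < min_frames:
        raise ValueError(f"need >= {min_frames} pre-onset frames, have {k}")
    return float(traj.diameters[:k].mean())


def running_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered running average with edge truncation (shrinking window)."""
    x = np.asarray(x, dtype=float)
    if window > len(x):
        raise ValueError("smoothing window exceeds trajectory length")
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        out[i] = x[max(0, i - half): i + half + 1].mean()
    return out


def peak_dilation(traj: DiameterTrajectory, search_s: float = 40.0,
                  smooth_window: int = 5) -> tuple[float, float]:
    """(Dp, relative dilation): max of the smoothed trajectory in the search
    window after stimulus onset, relative to the pre-onset baseline."""
    k = traj.window.onset_index
    onset_t = traj.times[k]
    if traj.times[-1] < onset_t + search_s - 1e-9:
        raise ValueError("trajectory does not cover the post-onset search window")
    d0 = baseline_diameter(traj)
    smooth = running_average(traj.diameters, smooth_window)
    in_win = (traj.times >= onset_t) & (traj.times <= onset_t + search_s)
    dp = float(smooth[in_win].max())
    return dp, (dp - d0) / d0


def qc_exclude(traj: DiameterTrajectory, cv_max: float = 0.10,
               pre_onset_k: float = 3.0) -> NvcResult:
    """Apply the two exclusion rules and compute the dilation metrics.

    (i) unstable baseline: pre-onset coefficient of variation above ``cv_max``;
    (ii) spontaneous dilation: any smoothed late-baseline value exceeding the
    early-baseline mean by ``pre_onset_k`` times the early-baseline CV (with a
    1% CV floor so a noise-free ramp is still caught).  The bound is anchored
    on the first half of the baseline — a pre-onset rise would otherwise
    inflate the very variability that sets its own threshold.  Excluded
    trajectories still report their metrics so the exclusion can be audited.
    """
    k = traj.window.onset_index
    d0 = baseline_diameter(traj)
    pre = traj.diameters[:k]
    cv = float(pre.std(ddof=0) / d0) if d0 > 0 else np.inf
    dp, rel = peak_dilation(traj)
    if cv > cv_max:
        return NvcResult(d0, dp, rel, True, "unstable baseline", traj.vessel_class)
    # smooth the pre-onset segment alone so post-onset frames cannot leak
    # into the centered window and mimic a spontaneous rise
    early = pre[: max(len(pre) // 2, 1)]
    ref = float(early.mean())
    cv_ref = max(float(early.std(ddof=0) / ref) if ref > 0 else np.inf, 0.01)
    smooth_pre = running_average(traj.diameters[:k])
    if np.any(smooth_pre > ref * (1 + pre_onset_k * cv_ref) + 1e-12):
        return NvcResult(d0, dp, rel, True, "spontaneous dilation", traj.vessel_class)
    return NvcResult(d0, dp, rel, False, "", traj.vessel_class)


def lfp_amplitude(train: LfpTrain, response_window_s: tuple[float, float] = (0.005, 0.100),
                  baseline_s: float = 0.050) -> float:
    """Mean evoked negative-peak amplitude (mV) over all pulses but the first.

    Per pulse: amplitude = |min of the trace within the response window minus
    the mean over the pre-pulse baseline window|.
    """
    if len(train.stimulus_times) < 2:
        raise ValueError("need at least 2 stimuli")
    gaps = np.diff(train.stimulus_times)
    if np.any(gaps < response_window_s[1]):
        raise ValueError("response windows overlap the next stimulus")
    fs = train.sample_rate
    amps = []
    for ts in train.stimulus_times:
        i = int(round(ts * fs))
        b0 = max(0, i - int(round(baseline_s * fs)))
        base = train.trace[b0:i].mean() if i > b0 else 0.0
        r0 = i + int(round(response_window_s[0] * fs))
        r1 = i + int(round(response_window_s[1] * fs))
        amps.append(abs(float(train.trace[r0:r1].min() - base)))
    train.amplitudes = np.asarray(amps)
    return float(np.mean(amps[1:]))
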