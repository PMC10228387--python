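"""Paracellular-leakage quantification: the AUC-ratio statistic.

Small-tracer leakage across the blood-brain barrier is scored as the ratio of
the area under the parenchymal intensity-time curve to the area under the
blood (pial vessel) curve, per cortical depth.  Dividing by the blood AUC
normalises away injection-to-injection differences in circulating tracer.
Traces come from small regions of interest whose positions are corrected for
rigid lateral drift and whose depths are resolved against an interpolated
brain-surface model; ROIs under vessels or plaques are rejected because those
structures shadow the parenchymal signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from .io import HyperStack, max_project

logger = logging.getLogger("nvuq")

__all__ = ["Roi", "RoiTrace", "LeakageResult", "estimate_lateral_drift",
           "extract_roi_traces", "trace_auc", "leakage_ratio", "measure_leakage"]


@dataclass
class Roi:
    """A rectangular region of interest in pixel coordinates (half-open)."""

    roi_id: str
    kind: str                    # "parenchyma" or "blood"
    x0: int
    y0: int
    x1: int
    y1: int
    depth_um: float | None = None   # parenchyma ROIs carry a target depth
    under_vessel: bool = False
    under_plaque: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("parenchyma", "blood"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "parenchyma" and self.depth_um is None:
            raise ValueError("parenchyma ROIs must carry a depth")
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty ROI box")


@dataclass
class RoiTrace:
    """Mean intensity within one ROI versus time (minutes from injection)."""

    roi_id: str
    times: np.ndarray       # min
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class LeakageResult:
    mouse_id: str
    ratio_by_depth: dict[float, float]
    auc_blood: float
    n_rois_by_depth: dict[float, int] = field(default_factory=dict)


def estimate_lateral_drift(frames: np.ndarray, confidence_floor: float = 0.1
                           ) -> np.ndarray:
    """Rigid per-frame (dy, dx) translation relative to frame 0, in pixels.

    ``frames`` is (T, Y, X), typically maximum-intensity projections.  Shifts
    are integer pixels from the phase-correlation peak.  When a frame carries
    no usable structure (normalised correlation at the estimated shift below
    ``confidence_floor``), the previous frame's drift is carried forward with
    a warning.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, Y, X) series with at least 2 frames")
    ref = frames[0]
    shifts = np.zeros((frames.shape[0], 2))
    for i in range(1, frames.shape[0]):
        cur = frames[i]
        if ref.std() == 0 or cur.std() == 0:
            ncc = 0.0
            shift = (0.0, 0.0)
        else:
            shift, _, _ = phase_cross_correlation(ref, cur, normalization=None)
            shift = np.rint(shift)
            rolled = np.roll(np.roll(cur, int(shift[0]), axis=0),
                             int(shift[1]), axis=1)
            a, b = ref - ref.mean(), rolled - rolled.mean()
            ncc = float((a * b).sum() / max(np.sqrt((a * a).sum() * (b * b).sum()), 1e-12))
        if ncc < confidence_floor:
            logger.warning("drift estimate unreliable at frame %d (ncc=%.2f); "
                           "carrying previous shift forward", i, ncc)
            shifts[i] = shifts[i - 1]
        else:
            # phase correlation returns the shift that maps frame -> ref;
            # the frame content moved by the negative of that
            shifts[i] = -np.asarray(shift)
    return shifts


def _roi_mean(frame: np.ndarray, roi: Roi, shift: np.ndarray) -> float:
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    y0 = np.clip(roi.y0 + dy, 0, frame.shape[0])
    y1 = np.clip(roi.y1 + dy, 0, frame.shape[0])
    x0 = np.clip(roi.x0 + dx, 0, frame.shape[1])
    x1 = np.clip(roi.x1 + dx, 0, frame.shape[1])
    if y1 <= y0 or x1 <= x0:
        raise ValueError(f"ROI {roi.roi_id} drifted out of the field")
    return float(frame[y0:y1, x0:x1].mean())


def extract_roi_traces(
    timelapse: HyperStack,
    rois: list[Roi],
    surface=None,
    *,
    channel: int = 0,
    drift_correct: bool = True,
) -> list[RoiTrace]:
    """Mean-intensity traces for each retained ROI at its nearest plane.

    The plane serving each parenchyma ROI is the one whose surface-relative
    depth (per-ROI, from the interpolated ``surface`` model when given,
    otherwise from the stack's plane depths) is nearest the ROI's requested
    depth, within one Z-step.  Blood ROIs read the shallowest plane.  ROIs
    flagged under-vessel or under-plaque are rejected with a log entry.
    """
    kept = []
    for roi in rois:
        if roi.under_vessel or roi.under_plaque:
            logger.info("ROI %s rejected (%s)", roi.roi_id,
                        "under vessel" if roi.under_vessel else "under plaque")
            continue
        kept.append(roi)
    if not kept:
        raise ValueError("all ROIs rejected")

    g = timelapse.geometry
    data = timelapse.data[:, :, channel]          # (T, Z, Y, X)
    shifts = np.zeros((timelapse.n_frames, 2))
    if drift_correct and timelapse.n_frames >= 2:
        shifts = estimate_lateral_drift(data.max(axis=1))
    times_min = timelapse.times() / 60.0

    plane_depths = timelapse.plane_depths()
    traces = []
    for roi in kept:
        if roi.kind == "blood":
            plane = 0
        else:
            if surface is not None:
                cx = 0.5 * (roi.x0 + roi.x1) * g.pixel_size_xy
                cy = 0.5 * (roi.y0 + roi.y1) * g.pixel_size_xy
                depths = plane_depths - float(surface.z_at(cx, cy))
            else:
                depths = plane_depths
            plane = int(np.argmin(np.abs(depths - roi.depth_um)))
            if abs(depths[plane] - roi.depth_um) > g.z_step:
                raise ValueError(
                    f"ROI {roi.roi_id}: requested depth {roi.depth_um} um not "
                    f"within one Z-step of any plane")
        vals = [_roi_mean(data[t, plane], roi, shifts[t])
                for t in range(timelapse.n_frames)]
        traces.append(RoiTrace(roi.roi_id, times_min, np.array(vals)))
    return traces


def trace_auc(trace: RoiTrace) -> float:
    """Trapezoidal area under the intensity-time curve (a.u. * min)."""
    if len(trace.times) < 2:
        raise ValueError("AUC requires at least 2 samples")
    return float(np.trapezoid(trace.intensities, trace.times))


def leakage_ratio(parenchyma_traces: list[RoiTrace], blood_trace: RoiTrace) -> float:
    """AUC ratio at one depth: ROI curves are averaged first, then integrated.

    Averaging the 4-5 parenchymal ROI curves before integration matches the
    per-depth averaging of the imaging protocol; with a common time base the
    order does not change the trapezoid value.
    """
    if not parenchyma_traces:
        raise ValueError("no parenchyma traces")
    for tr in parenchyma_traces:
        if not np.array_equal(tr.times, blood_trace.times):
            raise ValueError("traces must share a common time base")
    auc_b = trace_auc(blood_trace)
    if auc_b == 0:
        raise ValueError("zero blood AUC")
    mean_int = np.mean([tr.intensities for tr in parenchyma_traces], axis=0)
    mean_trace = RoiTrace("mean", blood_trace.times, mean_int)
    return trace_auc(mean_trace) / auc_b


def measure_leakage(
    timelapse: HyperStack,
    rois: list[Roi],
    surface=None,
    mouse_id: str = "",
    drift_correct: bool = True,
) -> LeakageResult:
    """Full per-recording pipeline: traces, then one AUC ratio per depth."""
    traces = extract_roi_traces(timelapse, rois, surface,
                                drift_correct=drift_correct)
    by_id = {t.roi_id: t for t in traces}
    blood = [r for r in rois if r.kind == "blood" and r.roi_id in by_id]
    if not blood:
        raise ValueError("no blood ROI retained")
    blood_ints = np.mean([by_id[r.roi_id].intensities for r in blood], axis=0)
    blood_trace = RoiTrace("blood", by_id[blood[0].roi_id].times, blood_ints)

    depths = sorted({r.depth_um for r in rois
                     if r.kind == "parenchyma" and r.roi_id in by_id})
    ratios, n_rois = {}, {}
    for d in depths:
        group = [by_id[r.roi_id] for r in rois
                 if r.kind == "parenchyma" and r.depth_um == d and r.roi_id in by_id]
        ratios[d] = leakage_ratio(group, blood_trace)
        n_rois[d] = len(group)
    return LeakageResult(mouse_id, ratios, trace_auc(blood_trace), n_rois)


def default_rois(timelapse: HyperStack, truth, depths=(20.0, 40.0, 80.0),
                 n_per_depth: int = 4, roi_um: float = 20.0, seed: int = 0
                 ) -> list[Roi]:
    """Place a blood ROI inside the generator's pial vessel and ``n_per_depth``
    parenchymal boxes per depth avoiding its flagged vessel-shadow and plaque
    regions.  A convenience for simulated recordings (the truth record knows
    the masks)."""
    rng = np.random.default_rng(seed)
    g = timelapse.geometry
    ny, nx = timelapse.data.shape[-2:]
    w = max(2, int(round(roi_um / g.pixel_size_xy)))
    bad = truth.blood_mask.copy()
    if truth.shadow_mask is not None:
        bad |= truth.shadow_mask
    if truth.plaque_mask is not None:
        bad |= truth.plaque_mask
    rois: list[Roi] = []
    ys, xs = np.where(truth.blood_mask)
    bx, by = int(xs.mean()), int(ys.mean())
    half = max(1, w // 4)
    rois.append(Roi("blood-0", "blood", bx - half, by - half, bx + half, by + half))
    for d in depths:
        placed = 0
        for _ in range(500):
            if placed >= n_per_depth:
                break
            x0 = int(rng.integers(0, nx - w))
            y0 = int(rng.integers(0, ny - w))
            if bad[y0:y0 + w, x0:x0 + w].any():
                continue
            rois.append(Roi(f"par-{d:g}-{placed}", "parenchyma",
                            x0, y0, x0 + w, y0 + w, depth_um=d))
            placed += 1
        if placed < n_per_depth:
            raise ValueError(f"could not place {n_per_depth} ROIs at depth {d}")
    return rois
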