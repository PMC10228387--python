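"""Hyperstack and tabular I/O.

Imaging data are held in memory as 5-D float arrays in fixed ``(T, Z, C, Y, X)``
order together with the physical voxel geometry.  On disk a hyperstack is a
multi-page TIFF of 16-bit unsigned pages accompanied by a sidecar
``*.geometry.json`` recording axis order, voxel geometry, channel labels and
the depth of plane 0 below the brain surface — TIFF axis tags vary too much
between dialects to be trusted alone.

Conventions used throughout the package:

* all coordinates are 0-based, intervals half-open;
* depths are in micrometres, positive downward from the brain surface,
  plane 0 being the shallowest;
* intensities are arbitrary units, stored as ``uint16`` on disk and computed
  in floating point in memory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("nvuq")

AXES = "TZCYX"

#: column schemas for every table the package reads or writes, in the
#: column order used on disk
SCHEMAS: dict[str, list[str]] = {
    "segments": ["mouse_id", "segment_id", "vessel_type", "length_um",
                 "diameter_um", "n_punctae"],
    "rois": ["mouse_id", "roi_id", "kind", "depth_um", "x0", "y0", "x1", "y1",
             "flags"],
    "surface_points": ["x_um", "y_um", "z_um"],
    "plaques": ["x_um", "y_um", "z_um"],
    "pericytes": ["mouse_id", "stack_id", "n_pericytes",
                  "total_capillary_length_um"],
    "lfp": ["time_s", "mV"],
    "stim_times": ["time_s"],
    "vessel_traces": ["trace_id", "vertex", "x_px", "y_px", "side"],
    "cohort": ["mouse_id", "group", "measure", "value", "age_months"],
    "cohort_truth": ["mouse_id", "group", "measure", "true_value"],
    "amt_cohort": ["mouse_id", "group", "vessel_type", "rho_per_um2"],
    "leakage": ["mouse_id", "depth_um", "ratio", "auc_blood", "n_rois"],
    "nvc": ["mouse_id", "vessel_class", "d0_um", "dp_um", "rel_dilation",
            "excluded", "reason"],
}


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of a voxel: XY pixel pitch, Z step, and frame period.

    Defaults match a high-zoom two-photon acquisition (0.124 um pixels,
    2.5 um optical sections).
    """

    pixel_size_xy: float = 0.124  # um per pixel
    z_step: float = 2.5           # um per plane
    time_step: float = 1.0        # s per frame

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "z_step", "time_step"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"VoxelGeometry.{name} must be strictly positive")


@dataclass
class HyperStack:
    """An imaging record: voxel grid over time and channels plus geometry.

    ``data`` is indexed ``(time, plane, channel, row, col)``.  ``origin_depth``
    is the depth (um below the brain surface) of plane 0.
    """

    data: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    channel_labels: list[str] = field(default_factory=list)
    origin_depth: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"HyperStack data must be 5-D {AXES}, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HyperStack intensities must be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[2])]
        if len(self.channel_labels) != self.data.shape[2]:
            raise ValueError("channel_labels length must equal channel count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    def plane_depths(self) -> np.ndarray:
        """Depth (um below surface) of every plane."""
        return self.origin_depth + np.arange(self.n_planes) * self.geometry.z_step

    def times(self) -> np.ndarray:
        """Acquisition time (s) of every frame."""
        return np.arange(self.n_frames) * self.geometry.time_step

    def channel(self, label: str) -> np.ndarray:
        """(T, Z, Y, X) view of a named channel."""
        return self.data[:, :, self.channel_labels.index(label)]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_name(path.with_suffix("").name + ".geometry.json")


def write_hyperstack(stack: HyperStack, path: str | Path) -> None:
    """Write a hyperstack as uint16 TIFF plus a ``*.geometry.json`` sidecar."""
    path = Path(path)
    arr = np.clip(np.rint(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)
    sidecar = {
        "axes": AXES,
        "shape": list(arr.shape),
        "pixel_size_xy_um": stack.geometry.pixel_size_xy,
        "z_step_um": stack.geometry.z_step,
        "time_step_s": stack.geometry.time_step,
        "channel_labels": stack.channel_labels,
        "origin_depth_um": stack.origin_depth,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_hyperstack(path: str | Path) -> HyperStack:
    """Read a multi-page TIFF into ``(T, Z, C, Y, X)`` order.

    A ``*.geometry.json`` sidecar, when present, is authoritative for the axis
    order and voxel geometry.  Without it, a plain 2-D TIFF is promoted to
    T=Z=C=1 and a TIFF whose embedded series axes are a subset of TZCYX is
    promoted accordingly; any other file is rejected rather than guessed at.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        axes = meta["axes"]
        geometry = VoxelGeometry(meta["pixel_size_xy_um"], meta["z_step_um"],
                                 meta["time_step_s"])
        labels = list(meta["channel_labels"])
        origin = float(meta.get("origin_depth_um", 0.0))
        arr = arr.reshape(meta["shape"])
    else:
        with tifffile.TiffFile(path) as tif:
            axes = tif.series[0].axes
        axes = axes.replace("S", "C").replace("I", "Z").replace("Q", "")
        if arr.ndim == 2:
            axes = "YX"
        if len(axes) != arr.ndim or not set(axes) <= set(AXES):
            raise ValueError(
                f"{path}: cannot resolve axes {axes!r} and no geometry sidecar; "
                "refusing to guess")
        logger.warning("%s: no geometry sidecar; using default voxel geometry", path)
        geometry = VoxelGeometry()
        labels, origin = [], 0.0
    # promote missing axes to length 1 and order as TZCYX
    for ax in AXES:
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    arr = np.moveaxis(arr, [axes.index(a) for a in AXES], range(5))
    return HyperStack(arr.astype(np.float64), geometry,
                      labels or [f"ch{i}" for i in range(arr.shape[2])], origin)


def max_project(stack: HyperStack, plane_range: tuple[int, int] | None = None) -> HyperStack:
    """Maximum-intensity projection along the optical (Z) axis.

    ``plane_range`` is a half-open ``(start, stop)`` interval of planes;
    ``None`` projects over all planes.  The result has a single Z plane.
    """
    if plane_range is None:
        plane_range = (0, stack.n_planes)
    lo, hi = plane_range
    if not (0 <= lo < hi <= stack.n_planes):
        raise ValueError(f"plane_range {plane_range} empty or out of bounds "
                         f"for {stack.n_planes} planes")
    proj = stack.data[:, lo:hi].max(axis=1, keepdims=True)
    return HyperStack(proj, stack.geometry, list(stack.channel_labels),
                      stack.origin_depth + lo * stack.geometry.z_step)


@dataclass
class AnnotationTable:
    """A typed table of annotation or result records.

    ``schema`` names one of the documented column layouts in :data:`SCHEMAS`;
    the underlying frame is a plain :class:`pandas.DataFrame` with exactly
    those columns.
    """

    schema: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.schema not in SCHEMAS:
            raise ValueError(f"unknown schema {self.schema!r}")
        cols = SCHEMAS[self.schema]
        missing = set(cols) - set(self.df.columns)
        if missing:
            raise ValueError(f"schema {self.schema!r} missing columns {sorted(missing)}")
        extra = set(self.df.columns) - set(cols)
        if extra:
            raise ValueError(f"schema {self.schema!r} has unexpected columns {sorted(extra)}")
        self.df = self.df[cols].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def write_results_table(table: AnnotationTable, path: str | Path) -> None:
    """Write a table as CSV with a header and stable column order."""
    table.df.to_csv(path, index=False, encoding="utf-8")


def read_results_table(path: str | Path, schema: str) -> AnnotationTable:
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty and list(df.columns) == SCHEMAS[schema]:
        df = df.astype({c: object for c in df.columns})
    return AnnotationTable(schema, df)
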