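"""Mask-based quantification and segmentation evaluation.

Operates on binary masks from any source — in practice the outputs of vessel
and punctae segmentation networks, here stood in for by synthetic truth masks
(optionally degraded).  The overlap metric is the Dice similarity coefficient

    DICE(yhat, y) = 2 * sum(yhat * y) / (sum(yhat) + sum(y)),

chosen in segmentation work for its robustness to the heavy class imbalance
between background and foreground pixels.  Vessel surface area from a 2-D
mask is ``n_pixels * pixel_area * pi`` (the projected strip wrapped into a
cylinder), so densities computed from masks are commensurate with the
annotation-based ``pi * d * l`` areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

logger = logging.getLogger("nvuq")

__all__ = ["MaskPair", "dice_coefficient", "vessel_area_from_mask",
           "count_punctae_components", "density_from_masks", "degrade_mask"]


@dataclass
class MaskPair:
    """A predicted and a ground-truth binary mask of identical shape."""

    prediction: np.ndarray
    ground_truth: np.ndarray
    pixel_size_um: float = 0.124

    def __post_init__(self) -> None:
        self.prediction = np.asarray(self.prediction)
        self.ground_truth = np.asarray(self.ground_truth)
        if self.prediction.shape != self.ground_truth.shape:
            raise ValueError("prediction and ground truth shapes differ")
        for m in (self.prediction, self.ground_truth):
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary (values in {0, 1})")


def dice_coefficient(pair: MaskPair) -> float:
    """Dice overlap in [0, 1]; undefined (error) when both masks are empty."""
    yhat = pair.prediction.astype(np.float64)
    y = pair.ground_truth.astype(np.float64)
    denom = yhat.sum() + y.sum()
    if denom == 0:
        raise ValueError("DICE undefined: both masks are empty")
    return float(2.0 * (yhat * y).sum() / denom)


def vessel_area_from_mask(vessel_mask: np.ndarray, pixel_size_um: float = 0.124) -> float:
    """Vessel lateral surface area (um^2) from a projected binary mask."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    n = int(np.count_nonzero(vessel_mask))
    if n == 0:
        logger.warning("vessel_area_from_mask: empty vessel mask, area 0")
    return n * pixel_size_um**2 * np.pi


def count_punctae_components(punctae_mask: np.ndarray, connectivity: int = 2) -> int:
    """Number of connected foreground components.

    ``connectivity`` follows :func:`skimage.measure.label`: 2 (the default)
    is 8-connectivity in 2-D, so diagonally touching punctae merge; pass 1
    for 4-connectivity.
    """
    mask = np.asarray(punctae_mask).astype(bool)
    return int(measure.label(mask, connectivity=connectivity).max())


def density_from_masks(
    vessel_masks: np.ndarray | list[np.ndarray],
    punctae_masks: np.ndarray | list[np.ndarray],
    pixel_size_um: float = 0.124,
    connectivity: int = 2,
) -> float:
    """Punctae per um^2 of vessel surface, pooled across ROIs before division.

    Accepts a single mask pair or parallel lists of ROI masks of one vessel
    type; counts and areas are summed first, then divided.
    """
    if isinstance(vessel_masks, np.ndarray):
        vessel_masks, punctae_masks = [vessel_masks], [punctae_masks]
    if len(vessel_masks) != len(punctae_masks):
        raise ValueError("need one punctae mask per vessel mask")
    total_n = 0
    total_a = 0.0
    for v, p in zip(vessel_masks, punctae_masks):
        if np.asarray(v).shape != np.asarray(p).shape:
            raise ValueError("vessel and punctae mask shapes differ")
        total_n += count_punctae_components(p, connectivity)
        total_a += vessel_area_from_mask(v, pixel_size_um)
    if total_a == 0:
        raise ValueError("zero total vessel area")
    return total_n / total_a


def degrade_mask(mask: np.ndarray, seed: int = 0, flip_frac: float = 0.1,
                 erode: bool = True) -> np.ndarray:
    """Morphologically degrade a truth mask to emulate an imperfect prediction.

    Used to build fixture predictions of network-like quality: boundary
    erosion plus salt noise at ``flip_frac`` of the foreground count.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(mask).astype(bool)
    if erode:
        out = morphology.erosion(out, morphology.footprint_rectangle((3, 3)))
    n_flip = int(flip_frac * np.count_nonzero(mask))
    if n_flip:
        idx = tuple(rng.integers(0, s, n_flip) for s in out.shape)
        out = out.copy()
        out[idx] = ~out[idx]
    return out.astype(np.uint8)
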