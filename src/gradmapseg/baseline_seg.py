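"""Deterministic ROI-constrained threshold segmenter.

This is plumbing, not a learned model: it exists so the evaluation and
analysis stages have a fully deterministic producer of predictions at desk
scale. Within each prior box it thresholds the normalised intensity (Otsu or
fixed), optionally keeps the largest connected component, and labels the
result with the box's source label. By construction the prediction can never
escape the ROI union — exactly the failure mode a box-prior method exhibits
when the tumor extends beyond its box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from gradmapseg.imaging_io import VolumeImage, LabelMask
from gradmapseg.gradmap import minmax_normalize
from gradmapseg.prior_roi import PriorROISet


@dataclass
class BaselineConfig:
    threshold_mode: str = "otsu"        # "otsu" | "fixed"
    fixed_threshold: float = 0.5        # normalised units, used when mode="fixed"
    smoothing_sigma: float = 1.0        # voxels; denoises before thresholding (0 = off)
    keep: str = "largest-component-per-box"   # | "all-components"
    label_priority: tuple[int, int] = (1, 2)  # first label wins in box overlaps

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"threshold_mode must be 'otsu' or 'fixed', got {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and not (0.0 <= self.fixed_threshold <= 1.0):
            raise ValueError(f"fixed_threshold must be in [0,1], got {self.fixed_threshold}")
        if self.keep not in ("largest-component-per-box", "all-components"):
            raise ValueError(f"unknown keep mode {self.keep!r}")


def _box_foreground(crop: np.ndarray, smooth_crop: np.ndarray, config: BaselineConfig) -> np.ndarray:
    # threshold seeded on the denoised crop (robust bimodal split), then moved
    # to the midpoint of the raw class means so the decision boundary stays
    # sharp at lesion edges
    if config.threshold_mode == "fixed":
        thr = config.fixed_threshold
    else:
        vals = smooth_crop.ravel()
        if np.ptp(vals) < 1e-6:     # flat box: Otsu undefined, predict nothing
            return np.zeros(crop.shape, dtype=bool)
        seed_thr = threshold_otsu(vals)
        hi = smooth_crop > seed_thr
        if not hi.any() or hi.all():
            return np.zeros(crop.shape, dtype=bool)
        thr = 0.5 * (float(crop[hi].mean()) + float(crop[~hi].mean()))
    fg = crop > thr
    if config.keep == "largest-component-per-box" and fg.any():
        labeled, n = ndimage.label(fg, structure=ndimage.generate_binary_structure(3, 3))
        if n > 1:
            sizes = ndimage.sum_labels(fg, labeled, index=np.arange(1, n + 1))
            fg = labeled == (1 + int(np.argmax(sizes)))
    return fg


def segment(image: VolumeImage, rois: PriorROISet, config: BaselineConfig | None = None) -> LabelMask:
    """Threshold within each perturbed prior box; zero outside all boxes.

    Overlapping boxes are resolved by label priority (primary over nodal by
    default): lower-priority labels are painted first and overwritten.
    """
    config = config or BaselineConfig()
    if rois.boxes and any(h > s for b in rois.boxes for h, s in zip(b.perturbed.hi, image.shape)):
        raise ValueError("ROI set extends beyond the image grid")
    normalized = minmax_normalize(image)
    raw = np.asarray(normalized.data, dtype=np.float64)
    if config.smoothing_sigma > 0:
        # smooth the full volume once so box faces see no filter edge effects
        smooth = ndimage.gaussian_filter(raw, sigma=config.smoothing_sigma, mode="reflect")
    else:
        smooth = raw
    pred = np.zeros(image.shape, dtype=np.uint8)
    for label in reversed(config.label_priority):
        for box in rois.boxes:
            if box.label != label:
                continue
            sl = box.perturbed.clip(image.shape).slices()
            fg = _box_foreground(raw[sl], smooth[sl], config)
            pred[sl][fg] = label
    return LabelMask(pred, image.spacing, affine=image.affine)
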