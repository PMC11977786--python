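"""Per-instance perturbed bounding boxes from a registered prior tumor mask.

Connected-component analysis finds individual tumor instances separately
within each label (primary and nodal instances never merge); each instance's
minimal axis-aligned box is expanded by an independent uniform draw of
2-6 voxels on every face, then clipped to the image. The expansion tolerates
residual registration error between the prior delineation and the tumor's
true position at the later timepoint.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from gradmapseg.imaging_io import LabelMask

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box: ``lo`` inclusive, ``hi`` exclusive, (z, y, x)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box: lo={self.lo}, hi={self.hi}")

    def contains(self, other: "BoundingBox") -> bool:
        return all(sl <= ol and oh <= sh for sl, ol, oh, sh in zip(self.lo, other.lo, other.hi, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def clip(self, shape: tuple[int, int, int]) -> "BoundingBox":
        return BoundingBox(
            lo=tuple(max(0, l) for l in self.lo),
            hi=tuple(min(s, h) for s, h in zip(shape, self.hi)),
        )

    def to_dict(self) -> dict:
        return {"lo": list(self.lo), "hi": list(self.hi)}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox":
        return cls(lo=tuple(d["lo"]), hi=tuple(d["hi"]))


@dataclass
class TumorInstance:
    """One connected tumor component of a single label."""

    label: int
    voxel_indices: np.ndarray  # (n, 3) int array of (z, y, x)
    voxel_count: int
    tight_box: BoundingBox


@dataclass
class ROIBox:
    label: int
    tight: BoundingBox
    perturbed: BoundingBox


@dataclass
class PriorROISet:
    """Perturbed per-instance boxes for one patient, with full provenance."""

    patient_id: str
    boxes: list[ROIBox] = field(default_factory=list)
    seed: int = 0
    source: str = "registered_pre"

    def union_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean support of the union of perturbed boxes."""
        out = np.zeros(shape, dtype=bool)
        for b in self.boxes:
            out[b.perturbed.clip(shape).slices()] = True
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "seed": self.seed,
                "source": self.source,
                "boxes": [
                    {"label": b.label, "tight": b.tight.to_dict(), "perturbed": b.perturbed.to_dict()}
                    for b in self.boxes
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PriorROISet":
        d = json.loads(text)
        return cls(
            patient_id=d["patient_id"],
            seed=d["seed"],
            source=d["source"],
            boxes=[
                ROIBox(
                    label=b["label"],
                    tight=BoundingBox.from_dict(b["tight"]),
                    perturbed=BoundingBox.from_dict(b["perturbed"]),
                )
                for b in d["boxes"]
            ],
        )


def extract_instances(mask: LabelMask, connectivity: int = 26) -> list[TumorInstance]:
    """Connected components per label value; labels never merge across values.

    Instances are sorted by (label, tight-box lo) for determinism.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {{6, 18, 26}}, got {connectivity}")
    structure = _STRUCTURES[connectivity]
    instances: list[TumorInstance] = []
    for label in (1, 2):
        support = mask.data == label
        if not support.any():
            continue
        labeled, n = ndimage.label(support, structure=structure)
        for comp in range(1, n + 1):
            idx = np.argwhere(labeled == comp)
            box = BoundingBox(lo=tuple(idx.min(axis=0).tolist()), hi=tuple((idx.max(axis=0) + 1).tolist()))
            instances.append(TumorInstance(label=label, voxel_indices=idx, voxel_count=len(idx), tight_box=box))
    instances.sort(key=lambda inst: (inst.label, inst.tight_box.lo))
    return instances


def tight_bbox(instance: TumorInstance) -> BoundingBox:
    """Minimal half-open box containing the instance's voxels."""
    if instance.voxel_count < 1:
        raise ValueError("cannot box an empty instance")
    return instance.tight_box


def perturb_bbox(
    box: BoundingBox,
    image_shape: tuple[int, int, int],
    rng: np.random.Generator,
    lo_margin: int = 2,
    hi_margin: int = 6,
    mode: str = "expand",
) -> BoundingBox:
    """Randomly perturb a box by 2-6 voxels per direction, clipped to the image.

    ``mode='expand'`` (default) pushes each of the six faces outward by an
    independent uniform integer draw from ``{lo_margin..hi_margin}``, so the
    result always contains the input before clipping. ``mode='shift'``
    translates the whole box by a signed per-axis draw instead.
    """
    if not (0 < lo_margin <= hi_margin):
        raise ValueError(f"need 0 < lo_margin <= hi_margin, got ({lo_margin}, {hi_margin})")
    if mode == "expand":
        lo_d = rng.integers(lo_margin, hi_margin + 1, size=3)
        hi_d = rng.integers(lo_margin, hi_margin + 1, size=3)
        new_lo = tuple(int(l - d) for l, d in zip(box.lo, lo_d))
        new_hi = tuple(int(h + d) for h, d in zip(box.hi, hi_d))
    elif mode == "shift":
        mag = rng.integers(lo_margin, hi_margin + 1, size=3)
        sign = np.where(rng.random(3) < 0.5, -1, 1)
        d = mag * sign
        new_lo = tuple(int(l + s) for l, s in zip(box.lo, d))
        new_hi = tuple(int(h + s) for h, s in zip(box.hi, d))
    else:
        raise ValueError(f"mode must be 'expand' or 'shift', got {mode!r}")
    return BoundingBox(lo=new_lo, hi=new_hi).clip(image_shape)


def _box_rng(seed: int, patient_id: str, box_index: int) -> np.random.Generator:
    # one substream per (seed, patient, box) so parallelism cannot reorder draws
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(patient_id.encode()), box_index]))


def build_roi_set(
    mask: LabelMask,
    patient_id: str,
    seed: int = 0,
    lo_margin: int = 2,
    hi_margin: int = 6,
    connectivity: int = 26,
    mode: str = "expand",
    source: str = "registered_pre",
) -> PriorROISet:
    """Extract instances, box them, and perturb each box reproducibly."""
    instances = extract_instances(mask, connectivity=connectivity)
    if not instances:
        logger.warning("patient %s: prior mask is tumor-free; empty ROI set", patient_id)
    boxes = []
    for i, inst in enumerate(instances):
        tight = tight_bbox(inst)
        perturbed = perturb_bbox(
            tight, mask.shape, _box_rng(seed, patient_id, i),
            lo_margin=lo_margin, hi_margin=hi_margin, mode=mode,
        )
        boxes.append(ROIBox(label=inst.label, tight=tight, perturbed=perturbed))
    return PriorROISet(patient_id=patient_id, boxes=boxes, seed=seed, source=source)


def save_roi_set(rois: PriorROISet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(rois.to_json())


def load_roi_set(path: str | Path) -> PriorROISet:
    return PriorROISet.from_json(Path(path).read_text())
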