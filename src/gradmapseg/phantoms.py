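"""Synthetic paired pre-/mid-treatment patients with known ground truth.

Each phantom patient carries a pre-treatment T2w-like image with ellipsoidal
lesions (one primary, up to a few nodal), a mid-treatment image in which each
lesion has shrunk by a drawn volume factor or disappeared, and a "registered
pre-treatment" mask: the pre-treatment lesion shapes translated by a small
drawn offset relative to the true mid-treatment lesion, emulating residual
deformable-registration error. Images are a two-level intensity model
(background + tumor contrast) plus additive Gaussian noise, so lesion edges
are analytically predictable for the gradient-map stage.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from gradmapseg.imaging_io import VolumeImage, LabelMask, write_volume, read_volume, read_mask

_PLACEMENT_RETRIES = 200


@dataclass
class PhantomConfig:
    """Study conditions for the phantom cohort.

    Defaults emulate a mid-treatment head-and-neck cohort at desk scale:
    anisotropic spacing matching thick-slice T2w acquisitions, one primary
    lesion plus up to two nodal lesions, volume shrink factors of 0.3-0.9
    between timepoints, a 10% chance a lesion disappears entirely, and a
    registration offset of at most one voxel per axis.
    """

    shape: tuple[int, int, int] = (16, 48, 48)
    spacing: tuple[float, float, float] = (1.2, 0.5, 0.5)
    n_gtvp: int = 1
    n_gtvn: int = 2
    pre_radius_range: tuple[float, float] = (3.0, 6.0)
    shrink_factor_range: tuple[float, float] = (0.3, 0.9)
    disappear_prob: float = 0.1
    #: (lo, hi) applied to every axis, or three (lo, hi) pairs in (z, y, x)
    #: order for axis-specific offsets (thick slices limit feasible z shifts)
    reg_offset_range: tuple = (0, 1)
    tumor_contrast: float = 0.3
    background_level: float = 0.2
    noise_sigma: float = 0.05
    bias_field: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.shrink_factor_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"shrink_factor_range must be ordered within [0,1], got {self.shrink_factor_range}")
        if not (0.0 <= self.disappear_prob <= 1.0):
            raise ValueError(f"disappear_prob must be in [0,1], got {self.disappear_prob}")
        a, b = self.pre_radius_range
        if a > b:
            raise ValueError(f"pre_radius_range must be ordered lo <= hi, got {(a, b)}")
        for lo, hi in self.offset_ranges():
            if lo > hi:
                raise ValueError(f"reg_offset_range entries must be ordered lo <= hi, got {(lo, hi)}")
        if not (0 <= self.n_gtvp <= 1):
            raise ValueError("n_gtvp must be 0 or 1")
        if not (0 <= self.n_gtvn <= 3):
            raise ValueError("n_gtvn must be between 0 and 3")

    def offset_ranges(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        """Registration-offset (lo, hi) per axis in (z, y, x) order."""
        r = self.reg_offset_range
        if len(r) == 3 and all(hasattr(e, "__len__") for e in r):
            return tuple(tuple(int(v) for v in e) for e in r)
        lo, hi = r
        return ((int(lo), int(hi)),) * 3


@dataclass
class LesionTruth:
    """Generator bookkeeping for one lesion."""

    label: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]      # pre-treatment, voxels
    shrink_factor: float                        # mid/pre volume ratio; 0 = disappeared
    disappeared: bool
    reg_offset: tuple[int, int, int]            # registered-mask translation, voxels


@dataclass
class PatientRecord:
    patient_id: str
    pre_image: VolumeImage
    pre_mask: LabelMask
    mid_image: VolumeImage
    mid_mask: LabelMask
    dr_pre_mask: LabelMask
    truth: list[LesionTruth] = field(default_factory=list)


class PlacementError(RuntimeError):
    """Raised when lesions cannot be placed without overlap."""


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    # stable per-patient substream; crc32 keeps entropy below 2**32
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(patient_id.encode())]))


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    if min(az, ay, ax) <= 0:
        return np.zeros(shape, dtype=bool)
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _place_lesions(config: PhantomConfig, rng: np.random.Generator) -> list[LesionTruth]:
    labels = [1] * config.n_gtvp + [2] * config.n_gtvn
    shape = np.array(config.shape, dtype=float)
    offset_ranges = config.offset_ranges()
    max_off = np.array([hi for _, hi in offset_ranges], dtype=float)
    lesions: list[LesionTruth] = []
    for label in labels:
        for _ in range(_PLACEMENT_RETRIES):
            r_lo, r_hi = config.pre_radius_range
            semi = rng.uniform(r_lo, r_hi, size=3)
            # slices are thicker than in-plane voxels: flatten along z so the
            # lesion fits small grids
            semi[0] = max(1.0, semi[0] * config.spacing[2] / config.spacing[0])
            # keep the lesion plus any registration offset inside the grid
            margin = semi + max_off + 1
            if np.any(shape - 2 * margin <= 0):
                continue
            center = np.array([rng.uniform(m, s - m) for m, s in zip(margin, shape)])
            # separation so translated registered shapes can never merge
            ok = all(
                np.linalg.norm(center - np.array(prev.center))
                > np.max(semi) + np.max(prev.semi_axes) + 2 * float(max_off.max()) + 2
                for prev in lesions
            )
            if not ok:
                continue
            if rng.uniform() < config.disappear_prob:
                shrink, disappeared = 0.0, True
            else:
                shrink = float(rng.uniform(*config.shrink_factor_range))
                disappeared = False
            offset = tuple(
                int(rng.integers(lo, hi + 1) * (1 if rng.uniform() < 0.5 else -1))
                for lo, hi in offset_ranges
            )
            lesions.append(
                LesionTruth(
                    label=label,
                    center=tuple(float(c) for c in center),
                    semi_axes=tuple(float(s) for s in semi),
                    shrink_factor=shrink,
                    disappeared=disappeared,
                    reg_offset=offset,
                )
            )
            break
        else:
            raise PlacementError(
                f"could not place a label-{label} lesion without overlap after "
                f"{_PLACEMENT_RETRIES} attempts; grid {config.shape} too small for config"
            )
    return lesions


def _paint(shape, lesions, which: str) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.uint8)
    for les in lesions:
        center = np.array(les.center)
        semi = np.array(les.semi_axes)
        if which == "mid":
            if les.disappeared:
                continue
            semi = semi * les.shrink_factor ** (1.0 / 3.0)  # volume factor -> semi-axes
        elif which == "dr_pre":
            center = center + np.array(les.reg_offset)
        support = _ellipsoid_mask(shape, center, semi)
        mask[support] = les.label
    return mask


def _render_image(mask: np.ndarray, config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    img = np.full(mask.shape, config.background_level, dtype=np.float64)
    img[mask > 0] += config.tumor_contrast
    if config.bias_field:
        z = np.linspace(-1, 1, mask.shape[0])[:, None, None]
        y = np.linspace(-1, 1, mask.shape[1])[None, :, None]
        img = img * (1.0 + 0.1 * z + 0.05 * y)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=mask.shape)
    return img.astype(np.float32)


def generate_patient(config: PhantomConfig, patient_id: str, rng: np.random.Generator) -> PatientRecord:
    """Generate one paired pre/mid phantom patient.

    Raises
    ------
    PlacementError
        If non-overlapping lesion placement fails after bounded retries.
    """
    lesions = _place_lesions(config, rng)
    pre = _paint(config.shape, lesions, "pre")
    mid = _paint(config.shape, lesions, "mid")
    dr_pre = _paint(config.shape, lesions, "dr_pre")
    spacing = config.spacing
    return PatientRecord(
        patient_id=patient_id,
        pre_image=VolumeImage(_render_image(pre, config, rng), spacing),
        pre_mask=LabelMask(pre, spacing),
        mid_image=VolumeImage(_render_image(mid, config, rng), spacing),
        mid_mask=LabelMask(mid, spacing),
        dr_pre_mask=LabelMask(dr_pre, spacing),
        truth=lesions,
    )


def generate_cohort(config: PhantomConfig, n_patients: int, seed: int | None = None) -> list[PatientRecord]:
    """Generate a reproducible cohort; per-patient RNG derived from (seed, patient_id)."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    seed = config.seed if seed is None else seed
    records = []
    for i in range(n_patients):
        pid = f"phantom_{i:03d}"
        records.append(generate_patient(config, pid, _patient_rng(seed, pid)))
    return records


def truth_volume_cc(record: PatientRecord, phase: str, label: int) -> float:
    """Volume of a label in a phase mask, in cubic centimetres.

    One voxel at spacing (1.2, 0.5, 0.5) mm is 0.3 mm^3 = 0.0003 cc.
    """
    if phase not in ("pre", "mid"):
        raise ValueError(f"phase must be 'pre' or 'mid', got {phase!r}")
    if label not in (1, 2):
        raise ValueError(f"label must be 1 or 2, got {label}")
    mask = record.pre_mask if phase == "pre" else record.mid_mask
    n = int(np.count_nonzero(mask.data == label))
    return n * mask.voxel_volume_mm3() / 1000.0


def save_cohort(records: list[PatientRecord], out_dir: str | Path, config: PhantomConfig | None = None) -> None:
    """Write a cohort as one directory per patient plus truth bookkeeping."""
    out_dir = Path(out_dir)
    for rec in records:
        pdir = out_dir / rec.patient_id
        write_volume(rec.pre_image, pdir / "preRT_T2.nii.gz")
        write_volume(rec.pre_mask, pdir / "preRT_mask.nii.gz")
        write_volume(rec.mid_image, pdir / "midRT_T2.nii.gz")
        write_volume(rec.mid_mask, pdir / "midRT_mask.nii.gz")
        write_volume(rec.dr_pre_mask, pdir / "preRT_mask_registered.nii.gz")
        (pdir / "truth.json").write_text(json.dumps([asdict(t) for t in rec.truth], indent=1))
    if config is not None:
        (out_dir / "phantom_config.json").write_text(json.dumps(asdict(config), indent=1))


def load_cohort(cohort_dir: str | Path) -> list[PatientRecord]:
    """Read a cohort written by :func:`save_cohort` back into records."""
    cohort_dir = Path(cohort_dir)
    records = []
    for pdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        truth_path = pdir / "truth.json"
        truth = []
        if truth_path.exists():
            truth = [
                LesionTruth(
                    label=t["label"],
                    center=tuple(t["center"]),
                    semi_axes=tuple(t["semi_axes"]),
                    shrink_factor=t["shrink_factor"],
                    disappeared=t["disappeared"],
                    reg_offset=tuple(t["reg_offset"]),
                )
                for t in json.loads(truth_path.read_text())
            ]
        records.append(
            PatientRecord(
                patient_id=pdir.name,
                pre_image=read_volume(pdir / "preRT_T2.nii.gz"),
                pre_mask=read_mask(pdir / "preRT_mask.nii.gz"),
                mid_image=read_volume(pdir / "midRT_T2.nii.gz"),
                mid_mask=read_mask(pdir / "midRT_mask.nii.gz"),
                dr_pre_mask=read_mask(pdir / "preRT_mask_registered.nii.gz"),
                truth=truth,
            )
        )
    if not records:
        raise FileNotFoundError(f"no patient directories found under {cohort_dir}")
    return records
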