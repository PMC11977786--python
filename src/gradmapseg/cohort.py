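"""Doubled pre+mid sample assembly, patient-level folds, and trainer export.

Each patient contributes two training units — a pre-treatment sample whose
ROIs come from its own ground-truth mask (a perfect prior), and a
mid-treatment sample whose ROIs come from the registered pre-treatment mask —
doubling the cohort (150 patients -> 300 samples). Folds are assigned at the
patient level so a patient's two samples always co-travel; validation uses
mid-treatment samples only, giving the 240-train / 30-validation arithmetic
for a 150-patient 5-fold cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gradmapseg.imaging_io import VolumeImage, LabelMask, check_same_grid, write_volume
from gradmapseg.phantoms import PatientRecord
from gradmapseg.prior_roi import PriorROISet, build_roi_set
from gradmapseg.gradmap import GradMapConfig, GradientMap, compose_gradient_map

logger = logging.getLogger(__name__)


@dataclass
class CohortSample:
    sample_id: str
    patient_id: str
    phase: str                      # "pre" | "mid"
    channel0: VolumeImage           # T2w-like intensity
    channel1: GradientMap           # ROI-restricted gradient magnitude
    target: LabelMask
    prior_source: str               # mask that anchored the ROIs
    rois: PriorROISet = field(repr=False, default=None)


@dataclass
class FoldAssignment:
    k: int
    mapping: dict[str, int]         # patient_id -> fold index
    seed: int

    def patients_in_fold(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.mapping.items() if f == fold)

    def to_json(self) -> str:
        return json.dumps({"k": self.k, "seed": self.seed, "mapping": self.mapping}, indent=1, sort_keys=True)


def assemble_samples(
    records: list[PatientRecord],
    seed: int = 0,
    gradcfg: GradMapConfig | None = None,
    lo_margin: int = 2,
    hi_margin: int = 6,
    connectivity: int = 26,
) -> list[CohortSample]:
    """Build exactly two samples per patient (phases pre and mid)."""
    gradcfg = gradcfg or GradMapConfig()
    samples: list[CohortSample] = []
    for rec in records:
        for img, msk in ((rec.pre_image, rec.pre_mask), (rec.mid_image, rec.mid_mask)):
            check_same_grid(img, msk, f"patient {rec.patient_id} image/mask")
        check_same_grid(rec.mid_image, rec.dr_pre_mask, f"patient {rec.patient_id} mid grid")

        for phase, image, prior_mask, target, source in (
            ("pre", rec.pre_image, rec.pre_mask, rec.pre_mask, "pre_gt"),
            ("mid", rec.mid_image, rec.dr_pre_mask, rec.mid_mask, "registered_pre"),
        ):
            rois = build_roi_set(
                prior_mask, rec.patient_id, seed=seed,
                lo_margin=lo_margin, hi_margin=hi_margin,
                connectivity=connectivity, source=source,
            )
            if not rois.boxes:
                logger.warning(
                    "patient %s (%s): tumor-free prior mask; gradient channel is all zero",
                    rec.patient_id, phase,
                )
            gmap = compose_gradient_map(image, rois, gradcfg)
            samples.append(
                CohortSample(
                    sample_id=f"{rec.patient_id}_{phase}",
                    patient_id=rec.patient_id,
                    phase=phase,
                    channel0=image,
                    channel1=gmap,
                    target=target,
                    prior_source=source,
                    rois=rois,
                )
            )
    return samples


def make_folds(patient_ids: list[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle + round-robin: fold sizes differ by at most one."""
    if k > len(patient_ids):
        raise ValueError(f"k={k} exceeds number of patients ({len(patient_ids)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = list(patient_ids)
    np.random.default_rng(seed).shuffle(order)
    mapping = {pid: i % k for i, pid in enumerate(order)}
    return FoldAssignment(k=k, mapping=mapping, seed=seed)


def split_fold(
    samples: list[CohortSample], assignment: FoldAssignment, fold: int
) -> tuple[list[CohortSample], list[CohortSample]]:
    """Train = both phases of out-of-fold patients; val = mid samples in-fold."""
    missing = {s.patient_id for s in samples} - set(assignment.mapping)
    if missing:
        raise ValueError(f"fold assignment is missing patients: {sorted(missing)}")
    train = [s for s in samples if assignment.mapping[s.patient_id] != fold]
    val = [s for s in samples if assignment.mapping[s.patient_id] == fold and s.phase == "mid"]
    return train, val


def export_trainer_layout(
    samples: list[CohortSample], assignment: FoldAssignment, out_dir: str | Path
) -> pd.DataFrame:
    """Write a channel-suffix trainer dataset layout and return the manifest.

    Layout: ``imagesTr/<id>_0000.nii.gz`` (intensity), ``<id>_0001.nii.gz``
    (gradient map), ``labelsTr/<id>.nii.gz``, a dataset JSON naming channels
    and labels, and a splits JSON mirroring the fold assignment.
    """
    out_dir = Path(out_dir)
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample id collision in cohort")
    (out_dir / "imagesTr").mkdir(parents=True, exist_ok=True)
    (out_dir / "labelsTr").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        write_volume(s.channel0, out_dir / "imagesTr" / f"{s.sample_id}_0000.nii.gz")
        write_volume(s.channel1.as_volume(), out_dir / "imagesTr" / f"{s.sample_id}_0001.nii.gz")
        write_volume(s.target, out_dir / "labelsTr" / f"{s.sample_id}.nii.gz")
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "phase": s.phase,
                "fold": assignment.mapping[s.patient_id],
                "prior_source": s.prior_source,
                "n_boxes": len(s.rois.boxes) if s.rois else 0,
            }
        )
    dataset = {
        "channel_names": {"0": "T2w", "1": "gradient_map"},
        "labels": {"background": 0, "GTVp": 1, "GTVn": 2},
        "numTraining": len(samples),
        "file_ending": ".nii.gz",
        # pre-phase priors anchor on the pre-treatment ground-truth mask itself
        "notes": "pre-phase ROIs use the ground-truth pre mask as a perfect prior",
    }
    (out_dir / "dataset.json").write_text(json.dumps(dataset, indent=1, sort_keys=True))
    splits = [
        {
            "train": sorted(s.sample_id for s in split_fold(samples, assignment, f)[0]),
            "val": sorted(s.sample_id for s in split_fold(samples, assignment, f)[1]),
        }
        for f in range(assignment.k)
    ]
    (out_dir / "splits_final.json").write_text(json.dumps(splits, indent=1))
    manifest = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
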