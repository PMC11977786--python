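"""Per-case and cohort segmentation metrics with challenge-style conventions.

Definitions
-----------
DSC
    2|A∩B| / (|A|+|B|) for two binary masks; 1.0 by convention when both
    masks are empty.
Aggregated DSC (``dsc_agg``)
    Intersections and mask sizes are summed over the whole cohort *before*
    forming the ratio, so empty cases contribute nothing rather than a 0 or 1
    — the ranking metric of cohort segmentation challenges.
HD95 / MSD
    95th percentile and mean of the pooled surface-to-surface distances (in
    mm, anisotropic spacing applied) between the two mask borders. Cases
    where exactly one of ground truth and prediction is empty have no
    meaningful surfaces and are excluded from surface metrics; the DSC for
    such a case is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from gradmapseg.imaging_io import LabelMask


@dataclass
class CaseMetrics:
    sample_id: str
    label: int
    dsc: float
    hd95_mm: float | None
    msd_mm: float | None
    surface_valid: bool
    reason: str
    gt_voxels: int
    pred_voxels: int
    intersection_voxels: int


@dataclass
class CohortMetrics:
    label: int
    dsc_agg: float
    mean_dsc: float
    mean_hd95_mm: float | None
    mean_msd_mm: float | None
    n_cases: int
    n_excluded_surface: int


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def dice(gt, pred) -> float:
    """Dice similarity coefficient of two binary masks; both empty -> 1.0."""
    gt, pred = _as_bool(gt), _as_bool(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    denom = int(gt.sum()) + int(pred.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(gt & pred)) / denom


def dsc_agg(cases: Iterable[tuple[np.ndarray, np.ndarray]]) -> float:
    """Aggregated Dice: ratio of sums across all cases.

    numerator = 2·Σ|gt∩pred|, denominator = Σ(|gt|+|pred|); an
    empty-everywhere cohort degenerates to 1.0 (documented convention).
    """
    num = denom = 0
    n = 0
    for gt, pred in cases:
        gt, pred = _as_bool(gt), _as_bool(pred)
        if gt.shape != pred.shape:
            raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
        num += 2 * int(np.count_nonzero(gt & pred))
        denom += int(gt.sum()) + int(pred.sum())
        n += 1
    if n == 0:
        raise ValueError("dsc_agg requires at least one case")
    return num / denom if denom > 0 else 1.0


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """Surface voxels by 6-connectivity erosion difference; (n, 3) indices."""
    mask = _as_bool(mask)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    return np.argwhere(mask & ~eroded)


def surface_distances(gt, pred, spacing: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Directed border-to-border nearest distances in mm, both directions.

    Returns ``(d_gt_to_pred, d_pred_to_gt)``; each entry is the Euclidean
    distance (anisotropic spacing applied) from a border voxel of one mask to
    the nearest border voxel of the other.
    """
    gt, pred = _as_bool(gt), _as_bool(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    if not gt.any() or not pred.any():
        raise ValueError("surface distances need both masks nonempty; gate via case_validity")
    sp = np.asarray(spacing, dtype=float)
    b_gt = border_voxels(gt) * sp
    b_pr = border_voxels(pred) * sp
    d_gt = cKDTree(b_pr).query(b_gt, k=1)[0]
    d_pr = cKDTree(b_gt).query(b_pr, k=1)[0]
    return d_gt, d_pr


def hd95(directed_a: np.ndarray, directed_b: np.ndarray, variant: str = "pooled") -> float:
    """95th percentile Hausdorff distance in mm.

    Default pools both directed multisets and takes one linear-interpolation
    percentile; ``variant='max-of-directed'`` takes the max of the two
    directed 95th percentiles instead.
    """
    a, b = np.asarray(directed_a, float), np.asarray(directed_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("hd95 requires nonempty distance sets")
    if variant == "pooled":
        return float(np.percentile(np.concatenate([a, b]), 95))
    if variant == "max-of-directed":
        return float(max(np.percentile(a, 95), np.percentile(b, 95)))
    raise ValueError(f"unknown variant {variant!r}")


def msd(directed_a: np.ndarray, directed_b: np.ndarray) -> float:
    """Mean surface distance: arithmetic mean of the pooled distances, mm."""
    a, b = np.asarray(directed_a, float), np.asarray(directed_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("msd requires nonempty distance sets")
    return float(np.concatenate([a, b]).mean())


def case_validity(gt, pred) -> tuple[bool, str]:
    """Whether surface metrics are meaningful, and why not.

    Valid iff both masks are nonempty; reasons: ``empty-gt-fp`` (no tumor in
    ground truth, false-positive prediction), ``empty-pred-fn`` (tumor
    present, empty prediction), ``both-empty``, ``valid``.
    """
    gt, pred = _as_bool(gt), _as_bool(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    g, p = gt.any(), pred.any()
    if g and p:
        return True, "valid"
    if not g and not p:
        return False, "both-empty"
    if not g:
        return False, "empty-gt-fp"
    return False, "empty-pred-fn"


def evaluate_case(sample_id: str, label: int, gt: np.ndarray, pred: np.ndarray,
                  spacing: Sequence[float]) -> CaseMetrics:
    gt, pred = _as_bool(gt), _as_bool(pred)
    valid, reason = case_validity(gt, pred)
    d = dice(gt, pred)
    h = m = None
    if valid:
        da, db = surface_distances(gt, pred, spacing)
        h, m = hd95(da, db), msd(da, db)
    return CaseMetrics(
        sample_id=sample_id, label=label, dsc=d, hd95_mm=h, msd_mm=m,
        surface_valid=valid, reason=reason,
        gt_voxels=int(gt.sum()), pred_voxels=int(pred.sum()),
        intersection_voxels=int(np.count_nonzero(gt & pred)),
    )


def evaluate_cohort(
    pairs: list[tuple[str, LabelMask, LabelMask]],
    labels: Sequence[int] = (1, 2),
) -> tuple[list[CaseMetrics], dict[int, CohortMetrics]]:
    """Score (sample_id, gt, pred) mask pairs per label with validity gating.

    Returns one :class:`CaseMetrics` row per (sample, label) and one
    :class:`CohortMetrics` per label. Surface means are taken over valid
    cases only; exclusions are counted.
    """
    if not pairs:
        raise ValueError("evaluate_cohort requires at least one case")
    case_rows: list[CaseMetrics] = []
    cohort: dict[int, CohortMetrics] = {}
    for label in labels:
        per_label: list[CaseMetrics] = []
        agg_pairs = []
        for sample_id, gt, pred in pairs:
            if gt.shape != pred.shape:
                raise ValueError(f"{sample_id}: gt/pred shape mismatch")
            g, p = gt.data == label, pred.data == label
            per_label.append(evaluate_case(sample_id, label, g, p, gt.spacing))
            agg_pairs.append((g, p))
        valid = [c for c in per_label if c.surface_valid]
        cohort[label] = CohortMetrics(
            label=label,
            dsc_agg=dsc_agg(agg_pairs),
            mean_dsc=float(np.mean([c.dsc for c in per_label])),
            mean_hd95_mm=float(np.mean([c.hd95_mm for c in valid])) if valid else None,
            mean_msd_mm=float(np.mean([c.msd_mm for c in valid])) if valid else None,
            n_cases=len(per_label),
            n_excluded_surface=len(per_label) - len(valid),
        )
        case_rows.extend(per_label)
    return case_rows, cohort


def round_half_even(value: float, decimals: int) -> float:
    """Round to ``decimals`` with banker's rounding on the decimal value."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def summarize_folds(per_fold_values: Sequence[float], decimals: int = 3) -> float:
    """Cross-validation table average: arithmetic mean of the per-fold values,
    rounded half-even to the table's printed precision (3 decimals for Dice
    scores, 1 for mm distances)."""
    values = [float(v) for v in per_fold_values]
    if not values:
        raise ValueError("need at least one fold value")
    return round_half_even(float(np.mean(values)), decimals)
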