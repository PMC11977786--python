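"""Result analyses: paired condition comparison and volume-change correlation.

Two questions are answered here. First, does one segmentation condition
(e.g. with the gradient-map channel) outperform another on matched cases? —
a Wilcoxon signed-rank test on paired per-case Dice scores. Second, how does
segmentation accuracy relate to tumor volume change between timepoints? —
Spearman rank correlation of (volume change, Dice) within mid-treatment
volume bins, with vanished-tumor cases (mid volume = 0) reported separately
because their Dice is structurally zero-or-one rather than volume-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gradmapseg.imaging_io import LabelMask
from gradmapseg.metrics import dice
from gradmapseg.phantoms import PatientRecord

EXACT_N_MAX = 25   # exact signed-rank null up to here, normal approximation above


@dataclass
class WilcoxonResult:
    statistic: float        # W+ = sum of ranks of positive differences
    p_value: float | None   # None when all differences are zero
    n: int                  # pairs remaining after dropping zero differences
    exact: bool
    degenerate: bool


@dataclass
class PairedComparison:
    case_ids: list[str]
    dsc_a: list[float]
    dsc_b: list[float]
    result: WilcoxonResult


@dataclass
class BinnedCorrelation:
    label: int | None
    bin_edges: list[float]
    bins: list[dict] = field(default_factory=list)   # {lo, hi, n, rho, case_ids}
    zero_volume_cases: list = field(default_factory=list)


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by dynamic programming over the doubled mid-ranks.

    Mid-ranks are multiples of 1/2, so doubling makes them integers; the
    convolution counts sign assignments for every achievable W+ value, which
    equals full enumeration of the 2^n sign patterns.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(dsc_a: Sequence[float], dsc_b: Sequence[float]) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired scores (two-sided).

    Zero differences are dropped; ties get mid-ranks. The null distribution
    is exact for n <= 25 remaining pairs, a tie-corrected normal
    approximation above. All differences zero -> degenerate, p undefined.
    """
    a, b = np.asarray(dsc_a, float), np.asarray(dsc_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D sequences")
    if a.size < 1:
        raise ValueError("need at least one pair")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(statistic=0.0, p_value=None, n=0, exact=True, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_N_MAX:
        p = _signed_rank_exact_p(w_plus, ranks)
        return WilcoxonResult(statistic=w_plus, p_value=p, n=n, exact=True, degenerate=False)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, p_value=p, n=n, exact=False, degenerate=False)


def paired_comparison(dsc_a: dict[str, float], dsc_b: dict[str, float]) -> PairedComparison:
    """Compare two conditions on the cases present under both (matched by id)."""
    common = sorted(set(dsc_a) & set(dsc_b))
    if not common:
        raise ValueError("no cases present under both conditions")
    va = [dsc_a[c] for c in common]
    vb = [dsc_b[c] for c in common]
    return PairedComparison(case_ids=common, dsc_a=va, dsc_b=vb, result=wilcoxon_paired(va, vb))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho: Pearson correlation of mid-ranks (average ranks on ties).

    Returns NaN when either input is constant (correlation undefined).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if x.size < 3:
        raise ValueError("spearman needs n >= 3")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def volume_change_table(
    records: Sequence[PatientRecord],
    predictions: dict[str, LabelMask],
    labels: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Per-(patient, label) rows of pre/mid volumes (cc), volume change
    (pre minus mid), mid-phase Dice against the prediction, and a flag for
    vanished tumors (mid volume = 0)."""
    rows = []
    for rec in records:
        pred = predictions.get(rec.patient_id)
        if pred is None:
            continue
        vox_cc = rec.mid_mask.voxel_volume_mm3() / 1000.0
        for label in labels:
            pre_n = int(np.count_nonzero(rec.pre_mask.data == label))
            mid_n = int(np.count_nonzero(rec.mid_mask.data == label))
            if pre_n == 0 and mid_n == 0:
                continue    # label absent at both timepoints: nothing to relate
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "label": label,
                    "pre_cc": pre_n * vox_cc,
                    "mid_cc": mid_n * vox_cc,
                    "delta_cc": (pre_n - mid_n) * vox_cc,
                    "dsc": dice(rec.mid_mask.data == label, pred.data == label),
                    "mid_zero": mid_n == 0,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "label", "pre_cc", "mid_cc", "delta_cc", "dsc", "mid_zero"])


def binned_spearman(
    table: pd.DataFrame,
    bin_edges: Sequence[float] | None = None,
    n_bins: int = 3,
    label: int | None = None,
) -> BinnedCorrelation:
    """Per-bin Spearman rho of (volume change, Dice) over mid-volume bins.

    Positive-mid-volume cases are assigned to half-open bins on ``mid_cc``
    (the last bin is closed above); zero-volume cases never enter a bin and
    are listed separately. Default binning is equal-count quantiles of the
    positive mid volumes (tertiles for ``n_bins=3``); explicit ``bin_edges``
    reproduce a chosen binning. Bins with fewer than 3 cases, or degenerate
    ranks, report rho as NaN.
    """
    if label is not None:
        table = table[table["label"] == label]
    positive = table[~table["mid_zero"]].reset_index(drop=True)
    zero = table[table["mid_zero"]]
    if len(positive) < 1:
        raise ValueError("need at least one positive-mid-volume case")
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(positive["mid_cc"], qs))
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError(f"bin edges must be strictly increasing, got {bin_edges}")
    out = BinnedCorrelation(label=label, bin_edges=edges.tolist(),
                            zero_volume_cases=zero["patient_id"].tolist())
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        in_bin = (positive["mid_cc"] >= lo) & ((positive["mid_cc"] <= hi) if last else (positive["mid_cc"] < hi))
        sub = positive[in_bin]
        rho = spearman(sub["delta_cc"].to_numpy(), sub["dsc"].to_numpy()) if len(sub) >= 3 else float("nan")
        out.bins.append(
            {"lo": float(lo), "hi": float(hi), "n": int(len(sub)), "rho": rho,
             "case_ids": sub["patient_id"].tolist()}
        )
    return out
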