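# Methods

## Pipeline model

The package treats mid-treatment tumor segmentation as a prior-guided
problem. A registered pre-treatment delineation supplies *location* priors;
the image itself supplies *boundary* evidence. The two are combined as:

1. **Instance boxes.** Connected components are computed separately within
   each label of the prior mask (primary-tumor voxels and nodal voxels never
   merge into one instance, even when adjacent), using 26-connectivity by
   default. Each instance's minimal half-open bounding box is expanded
   outward by an integer drawn independently per face, uniformly from
   {2, …, 6} voxels, then clipped to the image. Expansion (rather than
   signed shifting) is the default because the margin exists to *tolerate*
   registration error without excluding tumor; the signed-shift reading is
   available as `perturb_bbox(..., mode="shift")`. Whether one draw should
   be shared per axis or drawn per face is ambiguous; per-face independence
   is the default and the per-axis variant falls out of the shift mode.
   No minimum component size is applied: a 1-voxel prior instance yields a
   box.
2. **Gradient channel.** The image is min-max normalised over its full
   intensity range (constant volumes map to zero). The Gaussian gradient
   magnitude at scale σ = 1 is computed on the **full** volume and only then
   masked to the union of perturbed boxes; filtering inside crops would
   manufacture spurious responses at box faces, which
   `GradMapConfig(crop_mode="crop")` demonstrates. Values are clamped to
   [0, clip_hi] with clip_hi = 1; no affine rescale precedes the clamp — the
   input already lives in [0, 1], so the clamp is interpreted as a hard
   safety clip, and a rescale that guaranteed max 1 would leave nothing to
   clip. σ is in voxel units by default (anisotropy-unaware);
   `sigma_units="mm"` divides by the per-axis spacing for the physical
   reading.
3. **Cohort doubling.** Pre- and mid-treatment images of one patient are
   treated as independent samples, each with a two-channel input (intensity,
   gradient map) and its own target mask. Mid-treatment samples anchor their
   boxes on the *registered* pre-treatment mask; pre-treatment samples
   anchor on their own ground-truth mask — a "perfect prior", the most
   literal reading of computing their maps "by a similar process" — and the
   perturbation is applied to both for symmetry. Folds are assigned at the
   patient level (seeded shuffle, round-robin), so both samples of a patient
   co-travel; validation keeps mid-treatment samples only. For 150 patients
   and 5 folds this yields 240 training and 30 validation samples per fold.

Axis convention everywhere: arrays are (z, y, x), 0-based, boxes half-open
[lo, hi); the NIfTI reader reorients from the on-disk (x, y, z) order and
the writer inverts it, so a voxel keeps its index through a round trip.
Masks are written as uint8 (lossless), images and gradient maps as float32.

## Evaluation protocol

- Per-case Dice is 2|∩|/(|A|+|B|), defined as 1.0 when both masks are empty.
- Aggregated Dice sums numerators and denominators over all cases before
  dividing, so empty-at-both-ends cases contribute nothing (unlike a mean of
  per-case Dice, which this package also reports). An empty-everywhere
  cohort degenerates to 1.0 by documented convention.
- Surface distances use 6-connectivity erosion-difference border voxels and
  nearest-neighbour distances in physical mm (anisotropic spacing applied),
  both directions. HD95 is the 95th linear-interpolation percentile of the
  *pooled* directed distances (the convention of the common medical
  distance-metric toolkits; a max-of-directed variant is available), MSD the
  pooled mean. Cases where exactly one of ground truth and prediction is
  empty are excluded from surface metrics with a recorded reason
  (`empty-gt-fp` / `empty-pred-fn` / `both-empty`); their Dice still counts.
- Fold-table averages are arithmetic means rounded half-even to the printed
  precision of the source tables: 3 decimals for Dice-type scores, 1 for mm
  distances, 2 for the mean test score.

## Statistical primitives

The Wilcoxon signed-rank test drops zero differences, mid-ranks ties, and
computes the exact two-sided p (doubling convention) for n ≤ 25 by dynamic
programming over the doubled mid-ranks — equivalent to enumerating all 2^n
sign assignments, which the tests verify by literal enumeration for n ≤ 12 —
and a tie-corrected normal approximation above, without continuity
correction. Spearman's ρ is the Pearson correlation of mid-ranks; it is NaN
(flagged, not raised) when either ranking is constant.

Binned correlation assigns positive-mid-volume cases to half-open bins on
mid-treatment volume (last bin closed above); vanished-tumor cases
(mid volume = 0) are structurally uninformative about the volume–accuracy
relationship and are listed separately. Default bin edges are equal-count
tertiles of the positive mid volumes, since published per-bin edges come
without a stated selection rule; explicit edges are accepted to reproduce
any chosen binning. Bins with n < 3 report ρ as undefined.

## Phantom generator

The generator emulates a paired longitudinal cohort, not MRI physics. Per
patient: one primary and up to two nodal ellipsoidal lesions placed without
overlap (z semi-axes are scaled by the in-plane/through-plane spacing ratio
so lesions fit thick-slice grids); a volume shrink factor drawn uniformly
from [0.3, 0.9] applied to the mid-treatment lesion as the cube root on each
semi-axis (so "volume change" is exact by construction), with probability
0.1 of complete disappearance; a per-lesion integer registration offset
(default 0–1 voxels per axis, i.e. below the 2-voxel lower box margin;
configurable per axis, since large through-plane shifts are infeasible on
thin grids) translating the "registered" prior mask; intensities equal to a
0.2 background plus 0.3 tumor contrast plus Gaussian noise of σ 0.05, with
an optional smooth bias field off by default so lesion edges stay
analytically predictable for the gradient stage. Grids default to
16 × 48 × 48 voxels at 1.2 × 0.5 × 0.5 mm — the clinical voxel spacing on a
desk-scale grid, chosen so full 150-patient cohorts run in seconds.

Determinism: every stage that draws randomness derives an independent
substream from (seed, patient id[, box index]) via hashed seed sequences, so
cohorts, ROI sets and exports are bit-reproducible and order-independent.

What passing phantom tests does **not** show: performance on real T2w
anatomy (texture, partial-volume effects, deformable — not rigid —
registration error, observer-variable ground truth), nor anything about a
trained network. The baseline segmenter (seeded Otsu threshold refined to
the midpoint of the raw class means, computed on a σ = 1 smoothed volume,
largest component per box, label priority primary > nodal in overlaps) is
deterministic plumbing that makes the evaluation and analysis stages
executable end-to-end; it shares only the ROI-confinement property with a
box-prior network — which is exactly the mechanism the phantom experiments
probe: sub-margin offsets give aggregated Dice ≥ 0.8–0.9 per label, offsets
beyond the margins confine predictions to stale boxes and collapse Dice,
and boxes around vanished lesions produce false positives.

## Numerical choices and degenerate inputs

- Gaussian derivatives use reflective boundaries (no border ramps on small
  volumes).
- Min-max normalising a constant volume returns zeros; Otsu inside a flat
  box predicts nothing; a tumor-free prior mask yields an empty ROI set and
  an all-zero gradient channel (logged, never an error).
- Percentiles are linear-interpolation order statistics throughout.
- Instance ordering (by label, then box corner) and sorted JSON keys keep
  serialised outputs byte-stable.
- Lesion placement retries 200 random positions before failing loudly;
  configurations whose offsets plus radii cannot fit the grid raise a
  placement error rather than silently clipping truth.

## Known limitations

Registration error is rigid per-lesion translation only; intensity is a
two-level model; no multi-observer consensus simulation; no DICOM or
cross-grid resampling (inputs are assumed co-registered); the Wilcoxon
normal approximation is used above n = 25 regardless of tie structure.
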