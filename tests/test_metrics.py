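import numpy as np
import pytest

from gradmapseg import (
    LabelMask, dice, dsc_agg, surface_distances, hd95, msd, case_validity,
    evaluate_cohort, summarize_folds,
)
from oracles import all_pairs_directed_distances, percentile_linear

SPACING = (1.2, 0.5, 0.5)


def cube(shape=(8, 8, 8), lo=(2, 2, 2), hi=(6, 6, 6)):
    m = np.zeros(shape, dtype=bool)
    m[tuple(slice(a, b) for a, b in zip(lo, hi))] = True
    return m


class TestDice:
    def test_identical_nonempty(self):
        m = cube()
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        assert dice(cube(hi=(4, 4, 4)), cube(lo=(5, 5, 5), hi=(7, 7, 7))) == 0.0

    def test_hand_counted_overlap(self):
        gt = np.zeros((4, 4, 4), dtype=bool)
        pred = np.zeros((4, 4, 4), dtype=bool)
        gt[0, 0, :4] = True              # 4 voxels
        pred[0, 0, 2:4] = pred[0, 1, :2] = True   # 4 voxels, overlap 2
        assert dice(gt, pred) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert dice(z, z) == 1.0

    def test_symmetric(self, rng):
        a, b = rng.random((6, 6, 6)) < 0.3, rng.random((6, 6, 6)) < 0.3
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestDscAgg:
    def test_single_case_reduces_to_dice(self, rng):
        a, b = rng.random((6, 6, 6)) < 0.3, rng.random((6, 6, 6)) < 0.3
        assert dsc_agg([(a, b)]) == pytest.approx(dice(a, b))

    def test_empty_case_contributes_nothing(self):
        gt = np.zeros((4, 4, 4), dtype=bool)
        pred = np.zeros((4, 4, 4), dtype=bool)
        gt[0, 0, :4] = True
        pred[0, 0, 2:4] = pred[0, 1, :2] = True
        z = np.zeros((4, 4, 4), dtype=bool)
        # (|gt|,|pred|,|∩|) = (4,4,2) and (0,0,0): 2*2/8, unlike a mean of dice
        assert dsc_agg([(gt, pred), (z, z)]) == pytest.approx(0.5)
        assert np.mean([dice(gt, pred), dice(z, z)]) == pytest.approx(0.75)

    def test_permutation_invariant(self, rng):
        cases = [(rng.random((5, 5, 5)) < 0.4, rng.random((5, 5, 5)) < 0.4) for _ in range(4)]
        assert dsc_agg(cases) == pytest.approx(dsc_agg(cases[::-1]))

    def test_bounded_by_per_case_dice(self, rng):
        cases = []
        while len(cases) < 4:
            a, b = rng.random((5, 5, 5)) < 0.4, rng.random((5, 5, 5)) < 0.4
            if a.any() or b.any():
                cases.append((a, b))
        scores = [dice(a, b) for a, b in cases]
        assert min(scores) - 1e-12 <= dsc_agg(cases) <= max(scores) + 1e-12

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            dsc_agg([])


class TestSurfaceDistances:
    def test_identical_masks_all_zero(self):
        m = cube()
        da, db = surface_distances(m, m, SPACING)
        assert np.all(da == 0) and np.all(db == 0)

    def test_single_voxel_offset_closed_form(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[1, 1, 1] = True
        b[1, 2, 1] = True     # one voxel along y at 0.5 mm spacing
        da, db = surface_distances(a, b, SPACING)
        assert da.tolist() == [pytest.approx(0.5)]
        assert db.tolist() == [pytest.approx(0.5)]

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            a = rng.random((10, 10, 10)) < 0.25
            b = rng.random((10, 10, 10)) < 0.25
            a[5, 5, 5] = b[4, 4, 4] = True
            da, db = surface_distances(a, b, SPACING)
            np.testing.assert_allclose(np.sort(da), np.sort(all_pairs_directed_distances(a, b, SPACING)), atol=1e-9)
            np.testing.assert_allclose(np.sort(db), np.sort(all_pairs_directed_distances(b, a, SPACING)), atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            surface_distances(cube(), np.zeros((8, 8, 8), dtype=bool), SPACING)


class TestPercentileMetrics:
    def test_hd95_zero_for_identical(self):
        assert hd95(np.zeros(10), np.zeros(10)) == 0.0

    def test_hd95_robust_to_single_outlier(self):
        a = np.zeros(100)
        b = np.concatenate([np.zeros(99), [10.0]])
        assert hd95(a, b) < 10.0

    def test_hd95_matches_sort_and_index_oracle(self, rng):
        for _ in range(20):
            a = rng.random(rng.integers(1, 120)) * 10
            b = rng.random(rng.integers(1, 120)) * 10
            assert hd95(a, b) == pytest.approx(percentile_linear(np.concatenate([a, b]), 95))

    def test_hd95_max_of_directed_variant(self):
        a, b = np.array([1.0, 2.0]), np.array([5.0])
        assert hd95(a, b, variant="max-of-directed") == pytest.approx(5.0)

    def test_msd_pooled_mean(self):
        assert msd(np.array([1.0, 1.0]), np.array([3.0])) == pytest.approx(5.0 / 3.0)

    def test_msd_matches_oracle_on_blobs(self, rng):
        a = rng.random((8, 8, 8)) < 0.3
        b = rng.random((8, 8, 8)) < 0.3
        a[4, 4, 4] = b[3, 3, 3] = True
        da, db = surface_distances(a, b, SPACING)
        oracle = np.concatenate([all_pairs_directed_distances(a, b, SPACING),
                                 all_pairs_directed_distances(b, a, SPACING)]).mean()
        assert msd(da, db) == pytest.approx(oracle)


class TestCaseValidity:
    def test_empty_gt_false_positive(self):
        assert case_validity(np.zeros((3, 3, 3)), cube((3, 3, 3), (0, 0, 0), (2, 2, 2))) == (False, "empty-gt-fp")

    def test_tumor_missed_entirely(self):
        assert case_validity(cube((3, 3, 3), (0, 0, 0), (2, 2, 2)), np.zeros((3, 3, 3))) == (False, "empty-pred-fn")

    def test_both_empty(self):
        assert case_validity(np.zeros((3, 3, 3)), np.zeros((3, 3, 3))) == (False, "both-empty")

    def test_both_nonempty_valid(self):
        m = cube()
        assert case_validity(m, m) == (True, "valid")


class TestEvaluateCohort:
    def test_perfect_predictions(self, small_cohort):
        pairs = [(r.patient_id, r.mid_mask, r.mid_mask) for r in small_cohort]
        cases, cohort = evaluate_cohort(pairs)
        for cm in cohort.values():
            assert cm.dsc_agg == pytest.approx(1.0)
            assert cm.mean_hd95_mm == pytest.approx(0.0)
            assert cm.mean_msd_mm == pytest.approx(0.0)

    def test_one_row_per_sample_and_label(self, small_cohort):
        pairs = [(r.patient_id, r.mid_mask, r.dr_pre_mask) for r in small_cohort]
        cases, cohort = evaluate_cohort(pairs)
        assert len(cases) == 2 * len(pairs)
        for cm in cohort.values():
            assert cm.n_cases == len(pairs)

    def test_invalid_cases_do_not_enter_surface_means(self):
        gt1 = LabelMask(cube().astype(np.uint8), SPACING)
        pred1 = LabelMask(cube(lo=(3, 3, 3), hi=(7, 7, 7)).astype(np.uint8), SPACING)
        gt2 = LabelMask(cube().astype(np.uint8), SPACING)
        empty = LabelMask(np.zeros((8, 8, 8), dtype=np.uint8), SPACING)
        _, with_invalid = evaluate_cohort([("a", gt1, pred1), ("b", gt2, empty)], labels=(1,))
        _, without = evaluate_cohort([("a", gt1, pred1)], labels=(1,))
        assert with_invalid[1].mean_hd95_mm == pytest.approx(without[1].mean_hd95_mm)
        assert with_invalid[1].n_excluded_surface == 1


class TestSummarizeFolds:
    def test_identical_values_unchanged(self):
        assert summarize_folds([0.5] * 5, decimals=3) == 0.5

    def test_dice_average_at_three_decimals(self):
        assert summarize_folds([0.682, 0.493, 0.469, 0.636, 0.697], decimals=3) == 0.595
        assert summarize_folds([0.871, 0.786, 0.868, 0.859, 0.827], decimals=3) == 0.842

    def test_distance_average_at_one_decimal(self):
        assert summarize_folds([9.9, 15.6, 14.6, 9.3, 12.3], decimals=1) == 12.3
        assert summarize_folds([1.0, 1.4, 1.8, 1.6, 1.5], decimals=1) == 1.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_folds([])
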