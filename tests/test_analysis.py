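import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gradmapseg import (
    wilcoxon_paired, spearman, volume_change_table, binned_spearman,
    PhantomConfig, generate_cohort, truth_volume_cc,
)
from gradmapseg.analysis import paired_comparison
from oracles import wilcoxon_enumerate_p, spearman_by_hand


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        res = wilcoxon_paired([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.degenerate and res.p_value is None

    def test_six_positive_differences_exact_p(self):
        """All 6 differences positive: two-sided exact p = 2/2^6 = 0.03125."""
        a = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        b = [0.4, 0.45, 0.55, 0.6, 0.7, 0.75]
        res = wilcoxon_paired(a, b)
        assert res.exact
        assert res.p_value == pytest.approx(2 / 64)

    def test_exact_p_matches_sign_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            d = rng.normal(0.1, 0.3, n)
            d[d == 0] = 0.1
            a = rng.random(n)
            res = wilcoxon_paired(a + d, a)
            assert res.exact
            assert res.p_value == pytest.approx(wilcoxon_enumerate_p(d), abs=1e-12)

    def test_exact_p_with_tied_magnitudes(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.2, 0.2, -0.2, 0.4, 0.4])   # tied |differences|
        res = wilcoxon_paired(a, b)
        assert res.p_value == pytest.approx(wilcoxon_enumerate_p(a - b), abs=1e-12)

    def test_swapping_conditions_preserves_p(self, rng):
        a, b = rng.random(10), rng.random(10)
        ra, rb = wilcoxon_paired(a, b), wilcoxon_paired(b, a)
        assert ra.p_value == pytest.approx(rb.p_value)
        n = ra.n
        assert ra.statistic + rb.statistic == pytest.approx(n * (n + 1) / 2)

    def test_large_n_normal_approximation_tracks_scipy(self, rng):
        a = rng.random(40)
        b = a + rng.normal(0.05, 0.1, 40)
        res = wilcoxon_paired(a, b)
        assert not res.exact
        ref = stats.wilcoxon(a, b, correction=False, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_differences_dropped(self):
        res = wilcoxon_paired([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 2.5, 3.5])
        assert res.n == 2

    def test_paired_comparison_matches_only_common_cases(self):
        pc = paired_comparison({"a": 0.1, "b": 0.5, "c": 0.9}, {"b": 0.4, "c": 0.8, "d": 0.2})
        assert pc.case_ids == ["b", "c"]


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_matches_hand_rank_computation_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 6.0]
        assert spearman(x, y) == pytest.approx(spearman_by_hand(x, y), abs=1e-12)

    def test_matches_scipy_on_random_tied_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 50))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_undefined(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


@pytest.fixture(scope="module")
def cohort_with_predictions():
    cfg = PhantomConfig(disappear_prob=0.3)
    recs = generate_cohort(cfg, 12, seed=31)
    preds = {r.patient_id: r.mid_mask for r in recs}   # perfect predictions
    return recs, preds


class TestVolumeChangeTable:
    def test_volumes_match_truth_and_shrink(self, cohort_with_predictions):
        recs, preds = cohort_with_predictions
        table = volume_change_table(recs, preds)
        for row in table.itertuples():
            rec = next(r for r in recs if r.patient_id == row.patient_id)
            assert row.pre_cc == pytest.approx(truth_volume_cc(rec, "pre", row.label))
            assert row.mid_cc == pytest.approx(truth_volume_cc(rec, "mid", row.label))
            assert row.delta_cc == pytest.approx(row.pre_cc - row.mid_cc)

    def test_vanished_lesions_flagged(self, cohort_with_predictions):
        recs, preds = cohort_with_predictions
        table = volume_change_table(recs, preds)
        assert (table["mid_zero"] == (table["mid_cc"] == 0)).all()
        assert table["mid_zero"].any()     # disappear_prob=0.3 forces some

    def test_no_shrinkage_means_no_volume_change(self):
        cfg = PhantomConfig(disappear_prob=0.0, shrink_factor_range=(1.0, 1.0))
        recs = generate_cohort(cfg, 3, seed=5)
        table = volume_change_table(recs, {r.patient_id: r.mid_mask for r in recs})
        assert np.allclose(table["delta_cc"], 0.0)


class TestBinnedSpearman:
    def test_single_bin_reduces_to_global(self, cohort_with_predictions):
        recs, preds = cohort_with_predictions
        table = volume_change_table(recs, preds)
        sub = table[(table["label"] == 2) & ~table["mid_zero"]]
        edges = [sub["mid_cc"].min(), sub["mid_cc"].max()]
        bc = binned_spearman(table, bin_edges=edges, label=2)
        assert len(bc.bins) == 1
        assert bc.bins[0]["n"] == len(sub)
        expected = spearman(sub["delta_cc"].to_numpy(), sub["dsc"].to_numpy())
        if np.isnan(expected):
            assert np.isnan(bc.bins[0]["rho"])
        else:
            assert bc.bins[0]["rho"] == pytest.approx(expected)

    def test_constructed_monotone_bin_gives_minus_one(self):
        table = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(6)],
            "label": [1] * 6,
            "pre_cc": np.linspace(2, 4, 6),
            "mid_cc": np.full(6, 1.5),
            "delta_cc": np.linspace(0.5, 2.5, 6),
            "dsc": np.linspace(0.9, 0.4, 6),    # dsc strictly decreasing in delta
            "mid_zero": [False] * 6,
        })
        bc = binned_spearman(table, bin_edges=[1.0, 2.0], label=1)
        assert bc.bins[0]["rho"] == pytest.approx(-1.0)

    def test_zero_volume_cases_never_binned(self, cohort_with_predictions):
        recs, preds = cohort_with_predictions
        table = volume_change_table(recs, preds)
        bc = binned_spearman(table, label=1)
        binned_ids = {pid for b in bc.bins for pid in b["case_ids"]}
        zero_ids = set(table[(table["label"] == 1) & table["mid_zero"]]["patient_id"])
        assert binned_ids & zero_ids == set()
        assert set(bc.zero_volume_cases) == zero_ids

    def test_small_bins_undefined(self):
        table = pd.DataFrame({
            "patient_id": ["a", "b"], "label": [1, 1], "pre_cc": [2.0, 3.0],
            "mid_cc": [1.0, 2.0], "delta_cc": [1.0, 1.0], "dsc": [0.5, 0.6],
            "mid_zero": [False, False],
        })
        bc = binned_spearman(table, bin_edges=[0.5, 2.5], label=1)
        assert np.isnan(bc.bins[0]["rho"]) and bc.bins[0]["n"] == 2

    def test_unordered_edges_rejected(self, cohort_with_predictions):
        recs, preds = cohort_with_predictions
        table = volume_change_table(recs, preds)
        with pytest.raises(ValueError):
            binned_spearman(table, bin_edges=[3.0, 1.0], label=1)
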