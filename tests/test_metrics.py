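"""Group metrics against hand-computed sum-of-squares and counting oracles."""

import math

import numpy as np
import pytest

from olfbold.metrics import (
    RoiSet,
    dice,
    habituation_anova,
    icc,
    paired_compare,
    relative_difference,
    retest_dice,
    retest_icc,
    roi_summarize,
    roi_visibility_count,
)


def rm_anova_oracle(table):
    """One-way repeated-measures ANOVA from first principles."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    ss_treat = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((table - grand) ** 2).sum()
    ss_err = ss_tot - ss_treat - ss_subj
    ms_treat = ss_treat / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    f = ms_treat / ms_err
    from scipy import stats as sps

    p = sps.f.sf(f, k - 1, (n - 1) * (k - 1))
    return f, p


def icc2_oracle(x, y):
    """ICC(2,1) from the explicit two-way ANOVA table."""
    m = np.column_stack([x, y]).astype(float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((m - m.mean(axis=1, keepdims=True) - m.mean(axis=0) + grand) ** 2).sum()
        / ((n - 1) * (k - 1))
    )
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestHabituationAnova:
    def test_identical_blocks_give_f_zero(self):
        table = np.tile([[1.0], [2.0], [3.0]], (1, 3))
        f, p = habituation_anova(table)
        assert f == 0.0 and p == 1.0

    def test_small_table_matches_ss_oracle(self):
        table = np.array([[2.2, 0.9, -0.1], [1.8, 0.7, 0.2], [2.6, 1.1, 0.0]])
        f, p = habituation_anova(table)
        f0, p0 = rm_anova_oracle(table)
        assert f == pytest.approx(f0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)

    def test_random_tables_match_ss_oracle(self, rng):
        for _ in range(5):
            table = rng.normal(size=(6, 3)) + [2.0, 1.0, 0.0]
            f, p = habituation_anova(table)
            f0, p0 = rm_anova_oracle(table)
            assert f == pytest.approx(f0, rel=1e-9)
            assert p == pytest.approx(p0, rel=1e-6)

    def test_calibrated_group_rejects(self, rng):
        """Group tables with bulb-scale habituation reject in >=95% of runs."""
        from olfbold.phantom import simulate_subject_deltas

        hits = 0
        for _ in range(20):
            t = simulate_subject_deltas(5, (2.2, 0.8, -0.2), 0.0, 0.3, rng)
            hits += habituation_anova(t)[1] < 0.05
        assert hits >= 19

    def test_missing_cells_rejected(self):
        bad = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            habituation_anova(bad)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            habituation_anova(np.ones((1, 3)))


class TestRelativeDifference:
    def test_identical_blocks_zero(self):
        mean, se, per = relative_difference([2.0, 3.0], [2.0, 3.0])
        assert mean == 0.0 and se == 0.0

    def test_two_subject_example(self):
        mean, se, per = relative_difference([1.0, 1.0], [2.0, 2.0])
        assert mean == pytest.approx(-50.0)
        assert se == 0.0

    def test_matches_direct_formula(self, rng):
        dk = rng.normal(1.0, 0.4, size=10)
        d1 = rng.normal(2.0, 0.4, size=10)
        mean, se, per = relative_difference(dk, d1)
        direct = 100.0 * (dk - d1) / d1.mean()
        assert np.allclose(per, direct)
        assert mean == pytest.approx(direct.mean())
        assert se == pytest.approx(direct.std(ddof=1) / math.sqrt(10))

    def test_zero_group_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            relative_difference([1.0, 1.0], [1.0, -1.0])


class TestPairedCompare:
    def test_equal_conditions(self):
        a = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        out = paired_compare(a, a.copy())
        assert np.allclose(out["cohens_d"], 0.0)
        assert np.allclose(out["p_paired"], 1.0)

    def test_constant_offset_effect_size(self):
        b = np.array([[1.0], [2.0], [1.5]])  # sd 0.5
        a = b + 1.0
        out = paired_compare(a, b)
        assert out["cohens_d"].iloc[0] == pytest.approx(2.0)
        assert out["pooled_sd"].iloc[0] == pytest.approx(0.5)
        assert out["rel_diff_pct"].iloc[0] == pytest.approx(100.0 / 1.5)

    def test_matches_textbook_t(self, rng):
        from scipy import stats as sps

        a = rng.normal(1.0, 0.5, size=(8, 3))
        b = rng.normal(0.7, 0.5, size=(8, 3))
        out = paired_compare(a, b)
        for j in range(3):
            d = a[:, j] - b[:, j]
            t = d.mean() / (d.std(ddof=1) / math.sqrt(8))
            p = 2 * sps.t.sf(abs(t), 7)
            assert out["p_paired"].iloc[j] == pytest.approx(p, abs=1e-9)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_compare(np.ones((1, 2)), np.ones((1, 2)))


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4), bool)
        m[:2] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool); a[0] = True
        b = np.zeros((4, 4), bool); b[2] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_fixture(self):
        a = np.zeros(10, bool); a[:4] = True
        b = np.zeros(10, bool); b[2:6] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = rng.random((5, 5)) > 0.5
            b = rng.random((5, 5)) > 0.5
            assert dice(a, b) == dice(b, a)

    def test_empty_empty_is_one(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different grids"):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestIcc:
    def test_duplicated_data_is_exactly_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert icc(x, x.copy()) == pytest.approx(1.0)

    def test_reversed_fixture_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x[::-1].copy()
        val = icc(x, y)
        assert val == pytest.approx(icc2_oracle(x, y), abs=1e-9)
        assert val < 0

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = x + rng.normal(scale=0.5, size=6)
            assert icc(x, y) == pytest.approx(icc2_oracle(x, y), abs=1e-9)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=8)
        y = x + rng.normal(scale=0.3, size=8)
        long = pd.DataFrame({
            "targets": list(range(8)) * 2,
            "raters": ["a"] * 8 + ["b"] * 8,
            "scores": np.concatenate([x, y]),
        })
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="scores")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        icc3 = ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0]
        assert icc(x, y, "icc2") == pytest.approx(icc2, abs=1e-9)
        assert icc(x, y, "icc3") == pytest.approx(icc3, abs=1e-9)

    def test_variance_components_calibration(self, rng):
        """Measurement SD 0.33 on unit between-voxel SD -> mean ICC ~ 0.9."""
        vals = []
        for _ in range(100):
            truth = rng.normal(size=30)
            a = truth + rng.normal(scale=0.33, size=30)
            b = truth + rng.normal(scale=0.33, size=30)
            vals.append(icc(a, b))
        expect = 1.0 / (1.0 + 0.33**2)
        assert np.mean(vals) == pytest.approx(expect, abs=0.05)

    def test_noise_decreases_icc(self, rng):
        truth = rng.normal(size=50)
        small = icc(truth + rng.normal(scale=0.1, size=50),
                    truth + rng.normal(scale=0.1, size=50))
        big = icc(truth + rng.normal(scale=1.5, size=50),
                  truth + rng.normal(scale=1.5, size=50))
        assert small > big

    def test_zero_variance_returns_nan(self):
        assert math.isnan(icc(np.ones(4), np.ones(4)))


class TestRoiVisibility:
    def test_uniform_slice_counts_all(self):
        img = np.full((10, 10), 50.0)
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True
        assert roi_visibility_count(img, mask) == 4

    def test_suppressed_voxels_not_counted(self, rng):
        img = rng.normal(100.0, 1.0, size=(10, 10))
        mask = np.zeros((10, 10), bool)
        mask[0, :5] = True
        img[0, :5] = 0.0  # far below mean - 2 SD
        assert roi_visibility_count(img, mask) == 0

    def test_constructed_three_of_five(self):
        img = np.full((10, 10), 100.0)
        mask = np.zeros((10, 10), bool)
        mask[0, :5] = True
        img[0, 0] = -1000.0  # dropout-like voxels, far below mean - 2 SD
        img[0, 1] = -1000.0
        thr = img.mean() - 2 * img.std(ddof=1)
        assert img[0, 0] < thr < 100.0  # fixture sanity
        assert roi_visibility_count(img, mask) == 3

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_visibility_count(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestRoiSummaries:
    def make_maps(self):
        shape = (6, 6, 2)
        labels = np.zeros(shape, int)
        labels[:3, :3] = 1
        labels[3:, 3:] = 2
        sign = np.zeros(shape, np.int8)
        sign[:3, :3] = 1
        delta = np.zeros(shape + (3,))
        delta[:3, :3] = [2.0, 1.0, 0.5]
        tsnr = np.full(shape, 60.0)
        cnr = tsnr * delta[..., 0] / 100.0
        return labels, sign, delta, tsnr, cnr

    def test_single_roi_mean(self):
        labels, sign, delta, tsnr, cnr = self.make_maps()
        rs = RoiSet(labels, {1: "on", 2: "off"})
        out = roi_summarize(sign, delta, tsnr, cnr, rs, "positive")
        row = out[out.roi == "on"].iloc[0]
        assert row["n_active"] == 18
        assert row["delta_pct_block1"] == pytest.approx(2.0)
        assert row["cnr"] == pytest.approx(1.2)

    def test_empty_roi_flagged_missing(self):
        labels, sign, delta, tsnr, cnr = self.make_maps()
        rs = RoiSet(labels, {1: "on", 2: "off"})
        out = roi_summarize(sign, delta, tsnr, cnr, rs, "positive")
        row = out[out.roi == "off"].iloc[0]
        assert row["missing"]
        assert math.isnan(row["delta_pct_block1"])

    def test_unknown_label_rejected(self):
        labels, *_ = self.make_maps()
        with pytest.raises(ValueError, match="missing from the map"):
            RoiSet(labels, {1: "on", 9: "ghost"})

    def test_retest_dice_and_icc_tables(self, rng):
        labels, sign, delta, tsnr, cnr = self.make_maps()
        rs = RoiSet(labels, {1: "on", 2: "off"})
        out = retest_dice(sign, sign, rs)
        assert out.set_index("roi").loc["on", "dice"] == 1.0
        delta_b = delta + rng.normal(scale=0.05, size=delta.shape)
        icc_tab = retest_icc(sign, delta, delta_b, rs).set_index("roi")
        assert icc_tab.loc["on", "n_voxels"] == 18
        assert math.isnan(icc_tab.loc["off", "icc_block1"])
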