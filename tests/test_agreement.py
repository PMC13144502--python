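"""Agreement statistics: Bland-Altman, association, paired tests, ICC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nutrivalid import study
from nutrivalid.agreement import (
    bland_altman,
    icc_two_way_random,
    loa_from_summary,
    paired_compare,
    pearson_assoc,
    summary_from_convention,
)


class TestBlandAltman:
    def test_identical_pairs(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.loa == (0.0, 0.0)

    def test_hand_computed_small_sample(self):
        res = bland_altman(np.array([0.0, 0.0, 0.0]), np.array([1.0, 2.0, 3.0]))
        assert res.bias == pytest.approx(-2.0)
        assert res.sd_bias == pytest.approx(1.0)
        assert res.loa == pytest.approx((-3.96, -0.04))

    def test_published_summary_row_reconstructs_under_n_convention(self):
        """The app-vs-reference row: se_bias 329.7, se_loa 571.1 at n=20."""
        row = study.BA_VS_DLW["app"]
        rec = summary_from_convention(row["bias"], row["sd"], row["n"], "n")
        assert rec["se_bias"] == pytest.approx(row["se_bias"], abs=0.05)
        assert rec["se_loa"] == pytest.approx(row["se_loa"], abs=0.05)

    def test_loa_invariant_holds_exactly(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 30))
        res = bland_altman(a, b)
        assert res.loa[0] == res.bias - 1.96 * res.sd_bias
        assert res.loa[1] == res.bias + 1.96 * res.sd_bias

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_swapping_methods_mirrors_everything(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 15))
        ab = bland_altman(a, b)
        ba = bland_altman(b, a)
        assert ba.bias == pytest.approx(-ab.bias)
        assert ba.loa[0] == pytest.approx(-ab.loa[1])
        assert ba.loa[1] == pytest.approx(-ab.loa[0])
        assert ba.sd_bias == pytest.approx(ab.sd_bias)

    def test_se_ratio_is_sqrt_three(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 12))
        for convention in ("n", "n-1"):
            res = bland_altman(a, b, convention=convention)
            assert res.se_loa / res.se_bias == pytest.approx(np.sqrt(3.0), rel=1e-12)

    def test_single_pair_is_insufficient(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestLoaFromSummary:
    @pytest.mark.parametrize(
        "bias, sd, expected",
        [
            (-1479.5, 635.5, (-2725.08, -233.92)),
            (641.7, 1358.9, (-2021.74, 3305.14)),
            (0.0, 0.0, (0.0, 0.0)),
        ],
    )
    def test_limits(self, bias, sd, expected):
        assert loa_from_summary(bias, sd) == pytest.approx(expected, abs=0.01)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            loa_from_summary(0.0, -1.0)


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson_assoc(x, 2 * x + 1)
        assert res["r2"] == pytest.approx(1.0)
        assert res["signed_r2"] == pytest.approx(1.0)

    def test_perfect_inverse_line(self):
        x = np.arange(10.0)
        res = pearson_assoc(x, -x)
        assert res["r"] == pytest.approx(-1.0)
        assert res["signed_r2"] == pytest.approx(-1.0)

    def test_seeded_bivariate_normal_recovers_rho(self):
        """r within 3 SE of rho=0.5 at n=1000 (Fisher-z SE oracle)."""
        rng = np.random.default_rng(8)
        n, rho = 1000, 0.5
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        res = pearson_assoc(x, y)
        se_r = (1 - rho**2) / np.sqrt(n)
        assert abs(res["r"] - rho) < 3 * se_r

    def test_zero_variance_flagged_as_nan(self):
        res = pearson_assoc(np.ones(5), np.arange(5.0))
        assert np.isnan(res["r"])


class TestPairedCompare:
    def test_normal_differences_select_t(self):
        rng = np.random.default_rng(3)
        b = rng.normal(2000, 300, 40)
        a = b + rng.normal(-200, 100, 40)
        res = paired_compare(a, b)
        assert res["test"] == "paired_t"

    def test_skewed_differences_select_wilcoxon(self):
        rng = np.random.default_rng(4)
        b = rng.normal(2000, 10, 60)
        a = b + rng.lognormal(5, 1.2, 60)
        res = paired_compare(a, b)
        assert res["test"] == "wilcoxon"

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(5)
        b = rng.normal(size=30)
        a = b + rng.normal(0, 1, 30)  # null: raw p typically large
        res = paired_compare(a, b, bonferroni_k=3)
        assert res["p_adj"] == min(1.0, 3 * res["p_raw"])
        assert res["p_adj"] <= 1.0

    def test_constant_differences_are_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_compare(a + 5.0, a)
        assert res["test"] == "degenerate"


class TestIcc:
    def test_pure_between_subject_signal_gives_one(self):
        data = np.repeat(np.arange(5.0)[:, None], 4, axis=1)
        res = icc_two_way_random(data)
        assert res.icc == pytest.approx(1.0)

    def test_iid_noise_gives_zero(self):
        """500 x 7 i.i.d. matrix: ICC within 3 SE of 0 (Fisher variance)."""
        rng = np.random.default_rng(6)
        data = rng.normal(size=(500, 7))
        res = icc_two_way_random(data)
        k, n = 7, 500
        se = np.sqrt(2.0 / (k * (k - 1) * n))
        assert abs(res.icc) < 3 * se

    def test_equal_variance_components_give_half(self):
        rng = np.random.default_rng(7)
        n, k = 500, 7
        data = rng.normal(size=(n, 1)) + rng.normal(size=(n, k))
        res = icc_two_way_random(data)
        icc0 = 0.5
        se = np.sqrt(
            2 * (1 - icc0) ** 2 * (1 + (k - 1) * icc0) ** 2 / (k * (k - 1) * n)
        )
        assert abs(res.icc - icc0) < 3 * se

    def test_matches_brute_force_on_small_integer_matrix(self):
        """ICC(2,1) formula vs direct variance-component bookkeeping, 3x3."""
        data = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 5.0], [7.0, 8.0, 9.0]])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = (
            (data - data.mean(axis=1, keepdims=True)
             - data.mean(axis=0, keepdims=True) + grand) ** 2
        ).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_two_way_random(data)
        assert res.icc == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_reference(self):
        """Independent oracle: pingouin's ICC2 (absolute agreement, single)."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        n, k = 15, 4
        data = (
            rng.normal(0, 2, (n, 1))
            + rng.normal(0, 1.5, (n, k))
            + np.array([0.3, -0.2, 0.1, 0.0])
        )
        mine = icc_two_way_random(pd.DataFrame(data))
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "y": data.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subj", raters="rater", ratings="y")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert mine.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert mine.ci[0] == pytest.approx(row["CI95"][0], abs=0.01)
        assert mine.ci[1] == pytest.approx(row["CI95"][1], abs=0.01)

    def test_rows_with_missing_days_are_dropped(self):
        data = pd.DataFrame(np.random.default_rng(10).normal(size=(6, 3)))
        data.iloc[0, 1] = np.nan
        res = icc_two_way_random(data)
        assert res.n_dropped == 1
        assert res.n_subjects == 5

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            icc_two_way_random(np.ones((5, 1)))

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(11)
        data = rng.normal(0, 1, (20, 5)) + rng.normal(0, 1, (20, 1))
        res = icc_two_way_random(data)
        assert res.ci[0] <= res.icc <= res.ci[1]
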