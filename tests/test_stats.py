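"""Agreement and reliability statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from tubehct.errors import (
    ConfigError,
    DegenerateDataError,
    DesignError,
    InsufficientDataError,
)
from tubehct.stats import (
    GOOD_AGREEMENT_PCT,
    TrialTable,
    bland_altman,
    cohens_d,
    cohens_d_band,
    eta_sq_band,
    good_agreement_equivalent_hct,
    icc,
    paired_t_bonferroni,
    pearson_r,
    rm_anova,
    simulate_trial_table,
    typical_error,
)

# ---------------------------------------------------------------------------
# independent oracles: explicit mean-squares / sums-of-squares arithmetic
# ---------------------------------------------------------------------------


def icc2_oracle(grid: np.ndarray) -> float:
    """Two-way absolute-agreement single-measure ICC from raw mean squares."""
    n, k = grid.shape
    grand = grid.mean()
    msr = k * np.sum((grid.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((grid.mean(axis=0) - grand) ** 2) / (k - 1)
    sst = np.sum((grid - grand) ** 2)
    mse = (
        sst - (n - 1) * msr / k * k - (k - 1) * msc / n * n
    )  # SSE = SST - SSR - SSC
    mse = mse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def rm_anova_oracle(grid: np.ndarray) -> tuple[float, float]:
    """(F, partial eta squared) from explicit sums of squares."""
    n, k = grid.shape
    grand = grid.mean()
    ss_cond = n * np.sum((grid.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((grid.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((grid - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    return f, ss_cond / (ss_cond + ss_err)


def grid_to_table(grid: np.ndarray) -> TrialTable:
    records = [
        (f"S{i}", "r", f"m{j}", 1, float(grid[i, j]))
        for i in range(grid.shape[0])
        for j in range(grid.shape[1])
    ]
    return TrialTable.from_records(records)


# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([40, 42, 44], [40, 42, 44])
        assert res.mean_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.good_agreement

    def test_direct_arithmetic(self):
        res = bland_altman([1, 2, 3], [0, 0, 0])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(0.04)
        assert res.loa_high == pytest.approx(3.96)

    def test_good_agreement_threshold(self):
        x = np.array([40.0, 42.0, 44.0, 46.0])
        assert bland_altman(x + 1.3, x).good_agreement is False
        assert bland_altman(x + 1.1, x).good_agreement is True
        assert bland_altman(x - 1.3, x).good_agreement is False

    def test_antisymmetry(self, rng):
        x = rng.uniform(35, 50, 12)
        y = x + rng.normal(0, 1, 12)
        ab = bland_altman(x, y)
        ba = bland_altman(y, x)
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)
        assert ab.sd_diff == pytest.approx(ba.sd_diff)
        assert ab.loa_low == pytest.approx(-ba.loa_high)
        assert ab.loa_high == pytest.approx(-ba.loa_low)

    def test_constant_shift(self, rng):
        x = rng.uniform(35, 50, 12)
        y = x + rng.normal(0, 1, 12)
        base = bland_altman(x, y)
        shifted = bland_altman(x, y + 2.5)
        assert shifted.mean_diff == pytest.approx(base.mean_diff - 2.5)
        assert shifted.sd_diff == pytest.approx(base.sd_diff)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [2.0])
        with pytest.raises(InsufficientDataError):
            bland_altman([1, 2, 3], [1, 2])

    def test_threshold_equivalent_in_hct_points(self):
        # 1.2 % of a typical 45 % hematocrit is ~0.5 points, the mechanical
        # reader's smallest credible division
        assert GOOD_AGREEMENT_PCT == 1.2
        assert round(good_agreement_equivalent_hct(45.0), 1) == 0.5


class TestIcc:
    def test_identical_measurements_flagged_degenerate(self):
        rec = [(f"S{i}", "r", "m", t, 41.0) for i in range(5) for t in (1, 2, 3)]
        res = icc(TrialTable.from_records(rec), "intra")
        assert res.degenerate
        assert np.isnan(res.icc)
        assert res.typical_error == 0.0

    def test_duplicated_rater_gives_unity(self):
        rec = [
            (f"S{i}", r, "m", 1, 38.0 + 2 * i)
            for i in range(5)
            for r in ("novice", "expert")
        ]
        res = icc(TrialTable.from_records(rec), "inter")
        assert res.icc == pytest.approx(1.0)
        assert res.typical_error == 0.0

    def test_matches_mean_squares_oracle(self, rng):
        grid = rng.normal(42, 2, (5, 3)) + rng.normal(0, 0.6, (5, 3))
        rec = [
            (f"S{i}", "r", "m", j + 1, float(grid[i, j]))
            for i in range(5)
            for j in range(3)
        ]
        res = icc(TrialTable.from_records(rec), "intra")
        assert res.icc == pytest.approx(icc2_oracle(grid), rel=1e-9)
        assert res.icc_ci95[0] <= res.icc <= res.icc_ci95[1]

    def test_shift_invariance(self, rng):
        grid = rng.normal(42, 2, (6, 3))
        rec = lambda g: [
            (f"S{i}", "r", "m", j + 1, float(g[i, j]))
            for i in range(6)
            for j in range(3)
        ]
        a = icc(TrialTable.from_records(rec(grid)), "intra").icc
        b = icc(TrialTable.from_records(rec(grid + 3.0)), "intra").icc
        assert a == pytest.approx(b, rel=1e-12)

    def test_unbalanced_design_rejected(self):
        rec = [("S0", "r", "m", 1, 40.0), ("S0", "r", "m", 2, 41.0), ("S1", "r", "m", 1, 42.0)]
        with pytest.raises(DesignError):
            icc(TrialTable.from_records(rec), "intra")

    def test_mixed_raters_rejected_for_intra(self):
        rec = [("S0", r, "m", 1, 40.0) for r in ("a", "b")]
        with pytest.raises(DesignError):
            icc(TrialTable.from_records(rec), "intra")


class TestTypicalError:
    def test_known_differences(self):
        # two trials differing by exactly {1, 2, 3}: SD of diffs is 1
        grid = np.array([[40.0, 41.0], [42.0, 44.0], [44.0, 47.0]])
        assert typical_error(grid) == pytest.approx(1.0 / np.sqrt(2.0))

    def test_subject_offsets_do_not_matter(self, rng):
        grid = rng.normal(42, 1, (8, 3))
        shifted = grid + rng.normal(0, 5, (8, 1))  # per-subject constants
        assert typical_error(shifted) == pytest.approx(typical_error(grid))


class TestPearson:
    def test_perfect_linear(self):
        r, _ = pearson_r([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        r, _ = pearson_r([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_arithmetic(self, rng):
        x = rng.normal(42, 2, 6)
        y = 0.8 * x + rng.normal(0, 1, 6)
        r, p = pearson_r(x, y)
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expected, rel=1e-12)
        assert 0.0 <= p <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestRmAnova:
    def test_identical_conditions_zero_effect(self):
        grid = np.tile(np.array([[40.0], [42.0], [45.0]]), (1, 3))
        res = rm_anova(grid_to_table(grid), within_factor="method")
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)
        assert res.detail["ss_effect"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_sums_of_squares_oracle(self):
        grid = np.array([[40.0, 41.5], [43.0, 43.5], [45.0, 47.0]])
        res = rm_anova(grid_to_table(grid), within_factor="method")
        f, eta = rm_anova_oracle(grid)
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.effect_size == pytest.approx(eta, rel=1e-9)

    def test_eta_bounded_on_random_grids(self, rng):
        for _ in range(100):
            grid = rng.normal(42, 2, (4, 3))
            res = rm_anova(grid_to_table(grid), within_factor="method")
            assert 0.0 <= res.effect_size <= 1.0

    def test_incomplete_grid_rejected(self):
        rec = [("S0", "r", "a", 1, 40.0), ("S0", "r", "b", 1, 41.0), ("S1", "r", "a", 1, 42.0)]
        with pytest.raises(DesignError):
            rm_anova(TrialTable.from_records(rec), within_factor="method")


class TestPairedT:
    def test_identical_conditions(self):
        grid = np.tile(np.array([[40.0], [42.0], [45.0], [47.0]]), (1, 2))
        (res,) = paired_t_bonferroni(grid_to_table(grid), [("m0", "m1")])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_single_comparison_unadjusted(self, rng):
        grid = rng.normal(42, 2, (6, 2))
        (res,) = paired_t_bonferroni(grid_to_table(grid), [("m0", "m1")])
        assert res.p_value == pytest.approx(res.detail["p_raw"])

    def test_bonferroni_cap(self, rng):
        grid = rng.normal(42, 2, (6, 4))
        grid[:, 1:] += rng.normal(0, 0.05, (6, 3))  # weak effects -> large p
        comparisons = [("m0", "m1"), ("m0", "m2"), ("m0", "m3"), ("m1", "m2")]
        results = paired_t_bonferroni(grid_to_table(grid), comparisons)
        for res in results:
            assert res.p_value == min(1.0, res.detail["p_raw"] * 4)
            assert res.p_value <= 1.0

    def test_empty_comparisons_rejected(self):
        with pytest.raises(ConfigError):
            paired_t_bonferroni(grid_to_table(np.ones((3, 2))), [])


class TestCohensD:
    def test_equal_means(self):
        d, band = cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert d == 0.0
        assert band == "negligible"

    def test_direct_arithmetic(self):
        d, band = cohens_d([0.0, 2.0], [2.0, 4.0])
        assert d == pytest.approx(-2.0 / np.sqrt(2.0))
        assert band == "large"

    def test_antisymmetry_and_scale_invariance(self, rng):
        a = rng.normal(42, 2, 8)
        b = rng.normal(43, 2, 8)
        d_ab, _ = cohens_d(a, b)
        d_ba, _ = cohens_d(b, a)
        assert d_ab == pytest.approx(-d_ba)
        d_scaled, _ = cohens_d(3.7 * a, 3.7 * b)
        assert d_scaled == pytest.approx(d_ab)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    @pytest.mark.parametrize(
        "d, band",
        [(0.1, "negligible"), (0.3, "small"), (-0.3, "small"), (0.6, "medium"), (0.9, "large")],
    )
    def test_bands(self, d, band):
        assert cohens_d_band(d) == band

    @pytest.mark.parametrize(
        "eta, band",
        [(0.01, "negligible"), (0.05, "small"), (0.2, "medium"), (0.5, "large")],
    )
    def test_eta_bands(self, eta, band):
        assert eta_sq_band(eta) == band


class TestTrialTable:
    def test_duplicate_key_rejected(self):
        rec = [("S0", "r", "m", 1, 40.0), ("S0", "r", "m", 1, 41.0)]
        with pytest.raises(DesignError):
            TrialTable.from_records(rec)

    def test_out_of_range_rejected(self):
        with pytest.raises(DesignError):
            TrialTable.from_records([("S0", "r", "m", 1, 140.0), ("S1", "r", "m", 1, 40.0)])

    def test_csv_roundtrip(self, tmp_path):
        t = simulate_trial_table(4, 3, 2.0, 0.5, seed=2)
        path = tmp_path / "trials.csv"
        t.to_csv(path)
        back = TrialTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data[list(t.data.columns)], t.data, check_dtype=False
        )

    def test_simulated_variance_components(self):
        t = simulate_trial_table(200, 3, 3.0, 0.5, seed=4)
        grid = t.pivot("trial").to_numpy()
        assert grid.shape == (200, 3)
        # between-subject spread dominates within-subject spread as designed
        assert grid.mean(axis=1).std(ddof=1) > 5 * typical_error(grid)
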