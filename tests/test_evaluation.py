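"""Evaluation statistics: letter values, error summaries, ICC, decay fits."""

import math

import numpy as np
import pandas as pd
import pytest

from spinalign.evaluation import (
    DecayFit,
    heatmap_sd,
    heatmap_sd_decay,
    icc_analysis,
    icc_grade,
    icc_pair,
    letter_value_quantiles,
    parameter_error_summary,
)
from spinalign.heatmaps import TargetHeatmapSpec, target_heatmap


def quantile_oracle(sorted_x: np.ndarray, p: float) -> float:
    """Type-7 quantile by hand: linear interpolation of order statistics."""
    n = len(sorted_x)
    h = (n - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])


class TestLetterValues:
    def test_quartile_box_of_one_to_sixteen(self):
        table = letter_value_quantiles(np.arange(1, 17), depth=1)
        x = np.arange(1, 17, dtype=float)
        assert table.loc[1, "lower"] == pytest.approx(quantile_oracle(x, 0.25))
        assert table.loc[1, "upper"] == pytest.approx(quantile_oracle(x, 0.75))
        assert table.loc[0, "lower"] == pytest.approx(8.5)

    def test_constant_list_collapses(self):
        table = letter_value_quantiles([3.2] * 10, depth=4)
        assert (table == 3.2).all().all()

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(5.0, size=137)
        s = np.sort(x)
        table = letter_value_quantiles(x, depth=5)
        for k in range(1, 6):
            p = 2.0 ** -(k + 1)
            assert table.loc[k, "lower"] == pytest.approx(quantile_oracle(s, p))
            assert table.loc[k, "upper"] == pytest.approx(quantile_oracle(s, 1 - p))

    def test_intervals_are_nested_around_the_median(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(1.0, 1.0, size=500)
        table = letter_value_quantiles(x, depth=6)
        med = table.loc[0, "lower"]
        for k in range(1, 6):
            assert table.loc[k, "lower"] >= table.loc[k + 1, "lower"]
            assert table.loc[k, "upper"] <= table.loc[k + 1, "upper"]
            assert table.loc[k, "lower"] <= med <= table.loc[k, "upper"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            letter_value_quantiles([])


class TestParameterErrorSummary:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(2)
        truth = pd.DataFrame({"PI": rng.normal(52, 10, 30), "SS": rng.normal(36, 8, 30)})
        out = parameter_error_summary(truth.copy(), truth)
        assert (out["error_mean"] == 0).all()
        assert (out["wilcoxon_p"] == 1.0).all()
        assert np.allclose(out["pearson_r"], 1.0)

    def test_constant_input_flags_undefined_correlation(self):
        truth = pd.DataFrame({"PT": np.full(10, 15.0)})
        pred = pd.DataFrame({"PT": np.full(10, 15.0)})
        out = parameter_error_summary(pred, truth)
        assert not out.loc["PT", "r_defined"]
        assert np.isnan(out.loc["PT", "pearson_r"])
        assert out.loc["PT", "wilcoxon_p"] == 1.0

    def test_constant_offset_prediction(self):
        rng = np.random.default_rng(3)
        truth = pd.DataFrame({"LL": rng.normal(47, 12, 40)})
        pred = truth + 1.0
        out = parameter_error_summary(pred, truth)
        assert out.loc["LL", "error_mean"] == pytest.approx(1.0)
        assert out.loc["LL", "error_sd"] == pytest.approx(0.0)
        assert out.loc["LL", "pearson_r"] == pytest.approx(1.0)

    def test_folded_normal_mean_error(self):
        # |N(0, s)| has mean s*sqrt(2/pi)
        rng = np.random.default_rng(4)
        s = 3.0
        truth = pd.DataFrame({"GTK": rng.normal(38, 12, 10_000)})
        pred = truth + rng.normal(0, s, (10_000, 1))
        out = parameter_error_summary(pred, truth)
        expect = s * math.sqrt(2 / math.pi)
        assert out.loc["GTK", "error_mean"] == pytest.approx(expect, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            parameter_error_summary(
                pd.DataFrame({"PI": [1.0]}), pd.DataFrame({"PI": [1.0, 2.0]})
            )


def icc21_oracle(data: np.ndarray) -> float:
    """ICC(2,1) from two-way ANOVA mean squares, written from scratch."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_score_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert icc_pair(x, x.copy()) == pytest.approx(1.0)
        assert icc_grade(1.0) == "excellent"

    def test_matches_anova_oracle_on_handbuilt_table(self):
        data = np.array(
            [
                [9.0, 2.0, 5.0, 8.0],
                [6.0, 1.0, 3.0, 2.0],
                [8.0, 4.0, 6.0, 8.0],
                [7.0, 1.0, 2.0, 6.0],
                [10.0, 5.0, 6.0, 9.0],
                [6.0, 2.0, 4.0, 7.0],
            ]
        )
        # pairwise against the from-scratch mean-squares oracle
        for a in range(4):
            for b in range(a + 1, 4):
                pair = data[:, [a, b]]
                assert icc_pair(pair[:, 0], pair[:, 1]) == pytest.approx(
                    icc21_oracle(pair), abs=1e-9
                )

    def test_variance_components_recovery(self):
        rng = np.random.default_rng(5)
        st, se = 10.0, 5.0
        truth = rng.normal(0, st, 500)
        a = truth + rng.normal(0, se, 500)
        b = truth + rng.normal(0, se, 500)
        expect = st**2 / (st**2 + se**2)
        assert icc_pair(a, b) == pytest.approx(expect, abs=0.05)

    def test_symmetry_and_shift_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 5, 80)
        y = x + rng.normal(0, 2, 80)
        assert icc_pair(x, y) == pytest.approx(icc_pair(y, x), abs=1e-12)
        assert icc_pair(x + 7.0, y + 7.0) == pytest.approx(icc_pair(x, y), abs=1e-9)

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            icc_pair(np.full(10, 2.0), np.full(10, 2.0))

    def test_grades_cover_the_bands(self):
        assert icc_grade(0.95) == "excellent"
        assert icc_grade(0.8) == "high"
        assert icc_grade(0.6) == "moderate"
        assert icc_grade(0.3) == "low"
        assert icc_grade(0.1) == "poor"

    def test_analysis_matrix_and_orderings(self):
        rng = np.random.default_rng(7)
        truth = rng.normal(0, 10, 60)
        ratings = {
            "PI": pd.DataFrame({
                "R1": truth + rng.normal(0, 2, 60),
                "R2": truth + rng.normal(0, 2, 60),
                "AI": truth + rng.normal(0, 8, 60),
            }),
            "PT": pd.DataFrame({
                "R1": truth + rng.normal(0, 1, 60),
                "R2": truth + rng.normal(0, 1, 60),
                "AI": truth + rng.normal(0, 1, 60),
            }),
        }
        report = icc_analysis(ratings)
        assert report.icc.shape == (2, 3)
        assert set(report.row_order) == {"PI", "PT"}
        assert set(report.col_order) == {"R1-R2", "R1-AI", "R2-AI"}
        # the clean pair outranks pairs involving the noisy rater
        assert report.icc.loc["PI", "R1-R2"] > report.icc.loc["PI", "R1-AI"]
        assert (report.grades.loc["PT"] == "excellent").all()


class TestHeatmapSD:
    def test_one_hot_has_zero_spread(self):
        g = np.zeros((9, 9))
        g[4, 4] = 1.0
        assert heatmap_sd(g) == 0.0

    def test_discrete_gaussian_recovers_sigma(self):
        g = target_heatmap(40, 40, TargetHeatmapSpec("gaussian", 5.0), 80, 80)
        assert heatmap_sd(g) == pytest.approx(5.0, abs=0.1)

    def test_strictly_increasing_with_sigma(self):
        sds = [
            heatmap_sd(target_heatmap(40, 40, TargetHeatmapSpec("gaussian", s), 80, 80))
            for s in (1.0, 2.0, 4.0, 8.0)
        ]
        assert np.all(np.diff(sds) > 0)

    def test_unnormalised_grid_rejected(self):
        with pytest.raises(ValueError):
            heatmap_sd(np.ones((5, 5)))


class TestDecayFit:
    def test_noiseless_power_law_is_recovered_exactly(self):
        t = np.arange(1, 121)
        sds = pd.DataFrame({"thoracic": 5.0 * t**-0.5}, index=t)
        fit = heatmap_sd_decay(sds, window=(10, 100))["thoracic"]
        assert fit.gamma == pytest.approx(0.5, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.p_value < 1e-10

    def test_constant_series_has_zero_decay(self):
        t = np.arange(1, 121)
        sds = pd.DataFrame({"lumbar": np.full(120, 4.0)}, index=t)
        fit = heatmap_sd_decay(sds, window=(10, 100))["lumbar"]
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)

    def test_one_percent_noise_keeps_gamma_within_tolerance(self):
        rng = np.random.default_rng(8)
        t = np.arange(10, 101)
        y = 5.0 * t**-0.7 * (1 + 0.01 * rng.standard_normal(t.size))
        fit = heatmap_sd_decay(pd.DataFrame({"cervical": y}, index=t))["cervical"]
        assert fit.gamma == pytest.approx(0.7, abs=0.05)
        assert fit.adj_r2 > 0.95

    def test_landmark_columns_average_into_areas(self):
        t = np.arange(1, 101)
        sds = pd.DataFrame(
            {"lm1": 4.0 * t**-0.3, "lm2": 6.0 * t**-0.3, "lm3": 2.0 * t**-0.9},
            index=t,
        )
        fits = heatmap_sd_decay(sds, area_of={"lm1": "a", "lm2": "a", "lm3": "b"})
        assert fits["a"].gamma == pytest.approx(0.3, abs=0.01)
        assert fits["b"].gamma == pytest.approx(0.9, abs=1e-9)

    def test_nonpositive_sds_rejected(self):
        t = np.arange(1, 50)
        sds = pd.DataFrame({"x": np.linspace(1, -1, 49)}, index=t)
        with pytest.raises(ValueError, match="non-positive"):
            heatmap_sd_decay(sds, window=(1, 49))
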