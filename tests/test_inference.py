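"""Statistical cascade: exact-test oracles, screening, regression, ITS."""
import math

import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_p, grid_logit, mannwhitney_p, signed_rank_p
from dysglyc import (
    compare_paired,
    compare_unpaired,
    fisher_2x2,
    interrupted_time_series,
    logistic_cascade,
    screen_predictors,
)


class TestUnpaired:
    def test_identical_distributions_are_not_distinguished(self):
        res = compare_unpaired([1, 2, 3], [1, 2, 3], "rank")
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_groups_reach_minimal_exact_p(self):
        res = compare_unpaired([1, 2, 3], [10, 11, 12], "rank")
        assert res.p_value == pytest.approx(0.1)  # 2/20 rank configurations

    def test_rank_p_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            n, m = rng.integers(3, 6, size=2)
            a = rng.normal(0, 1, n).round(3)
            b = rng.normal(0.5, 1, m).round(3)
            if len(np.unique(np.concatenate([a, b]))) < n + m:
                continue
            res = compare_unpaired(a, b, "rank")
            assert res.p_value == pytest.approx(mannwhitney_p(a, b), abs=1e-10)

    def test_constant_data_is_degenerate(self):
        res = compare_unpaired([5.0, 5.0], [5.0, 5.0, 5.0], "rank")
        assert res.degenerate and res.p_value == 1.0

    def test_monotone_transform_leaves_rank_p_unchanged(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        p1 = compare_unpaired(a, b, "rank").p_value
        p2 = compare_unpaired(np.exp(a), np.exp(b), "rank").p_value
        assert p1 == pytest.approx(p2)

    def test_bootstrap_t_is_seed_deterministic_and_detects_shift(self, rng):
        a = rng.normal(100, 5, 25)
        b = rng.normal(130, 5, 25)
        r1 = compare_unpaired(a, b, "bootstrap_t", seed=4, n_boot=2000)
        r2 = compare_unpaired(a, b, "bootstrap_t", seed=4, n_boot=2000)
        assert r1.p_value == r2.p_value < 0.01

    def test_t_family_reports_mean_sd_summaries(self):
        res = compare_unpaired([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], "t")
        assert "±" in res.summaries["a"]
        assert res.p_value < 0.05


class TestPaired:
    def test_no_change_is_degenerate(self):
        res = compare_paired([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0

    def test_uniform_shift_of_eight_pairs_reaches_exact_floor(self):
        pre = np.arange(8, dtype=float) * 3 + 100
        res = compare_paired(pre, pre + 10)
        assert res.p_value == pytest.approx(2 / 2**8)

    def test_signed_rank_p_matches_sign_flip_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 11))
            pre = rng.normal(100, 10, n)
            post = pre + rng.normal(3, 5, n)
            res = compare_paired(pre, post)
            assert res.p_value == pytest.approx(signed_rank_p(pre, post), abs=1e-10)

    def test_pairs_with_missing_members_are_dropped(self):
        pre = [1.0, 2.0, np.nan, 4.0, 5.0]
        post = [2.0, 3.0, 9.0, 5.0, 6.0]
        res = compare_paired(pre, post)
        assert res.p_value == pytest.approx(2 / 2**4)

    def test_detects_post_onset_rise_in_generated_cohort(self, small_cohort):
        from dysglyc import compute_panels

        records, traces, _ = small_cohort
        panels = compute_panels(records, traces)
        frame = pd.DataFrame(
            [(p.patient_id, p.window, p.twag) for p in panels],
            columns=["pid", "window", "twag"],
        ).pivot(index="pid", columns="window", values="twag").dropna(subset=["pre", "post"])
        res = compare_paired(frame["pre"], frame["post"])
        assert res.p_value < 0.05
        assert frame["post"].median() > frame["pre"].median()


class TestFisher:
    def test_symmetric_table_gives_p_one(self):
        assert fisher_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_icu_mortality_contrast(self):
        # 19/70 deaths with the complication vs 9/81 without
        res = fisher_2x2([[19, 51], [9, 72]])
        assert round(res.p_value, 2) == 0.02

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            res = fisher_2x2(table)
            assert res.p_value == pytest.approx(fisher_p(table), rel=1e-9)

    def test_empty_margin_is_degenerate(self):
        res = fisher_2x2([[0, 4], [0, 7]])
        assert res.degenerate and res.p_value == 1.0


class TestScreening:
    @staticmethod
    def _features(rng, n=200):
        x1 = rng.normal(0, 1, n)
        x2 = 0.9 * x1 + math.sqrt(1 - 0.81) * rng.normal(0, 1, n)  # r ~ 0.9 with x1
        x3 = rng.normal(0, 1, n)
        logits = 1.5 * x1 + 0.5 * x3
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        return pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "outcome": y})

    def test_duplicated_predictor_is_retained_once(self, rng):
        df = self._features(rng)
        df["x1_copy"] = df["x1"]
        retained, log = screen_predictors(df, "outcome")
        assert ("x1" in retained) ^ ("x1_copy" in retained)
        assert any("retained" in line for line in log)

    def test_uncorrelated_predictors_all_survive(self, rng):
        n = 500
        df = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
                "outcome": (rng.random(n) < 0.4).astype(float),
            }
        )
        retained, _ = screen_predictors(df, "outcome")
        assert retained == ["a", "b", "c"]

    def test_more_predictive_member_of_correlated_pair_wins(self, rng):
        df = self._features(rng)
        retained, _ = screen_predictors(df, "outcome")
        assert "x1" in retained and "x2" not in retained and "x3" in retained

    def test_constant_predictor_is_excluded_and_logged(self, rng):
        df = self._features(rng, n=50)
        df["flat"] = 1.0
        retained, log = screen_predictors(df, "outcome")
        assert "flat" not in retained
        assert any("constant" in line for line in log)

    def test_screening_is_column_order_invariant(self, rng):
        df = self._features(rng)
        retained1, _ = screen_predictors(df, "outcome")
        shuffled = df[["x3", "x2", "outcome", "x1"]]
        retained2, _ = screen_predictors(shuffled, "outcome")
        assert set(retained1) == set(retained2)


class TestLogistic:
    def test_six_row_fit_matches_grid_likelihood_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        df = pd.DataFrame({"x": x, "outcome": y})
        uni, _ = logistic_cascade(df, "outcome")
        b0, b1 = grid_logit(x, y)
        assert uni.fits[0].coef == pytest.approx(b1, abs=1e-3)
        assert uni.fits[0].odds_ratio == pytest.approx(math.exp(b1), rel=1e-3)
        assert uni.fits[0].ci_low <= uni.fits[0].odds_ratio <= uni.fits[0].ci_high

    def test_null_predictor_has_unit_odds_ratio(self, rng):
        n = 4000
        df = pd.DataFrame(
            {"x": rng.normal(100, 10, n), "outcome": (rng.random(n) < 0.5).astype(float)}
        )
        uni, multi = logistic_cascade(df, "outcome")
        assert uni.fits[0].odds_ratio == pytest.approx(1.0, abs=0.02)
        assert multi.fits == []  # no candidate below alpha (overwhelmingly likely)

    def test_strong_predictor_enters_multivariable_model(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(1.2 * x)))).astype(float)
        df = pd.DataFrame({"x": x, "z": z, "outcome": y})
        uni, multi = logistic_cascade(df, "outcome")
        assert [f.predictor for f in multi.fits] == ["x"]
        assert multi.fits[0].odds_ratio > 1.5

    @pytest.mark.filterwarnings("ignore::RuntimeWarning", "ignore:Perfect separation")
    def test_separated_predictor_is_flagged(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0], "outcome": [0, 0, 0, 1, 1, 1.0]}
        )
        uni, multi = logistic_cascade(df, "outcome")
        assert uni.fits[0].flag is not None
        assert multi.fits == []


class TestITS:
    @staticmethod
    def _series(pre_level, post_level, pre_slope=0.0, post_slope=0.0, m=5, noise=None):
        pts = []
        for k in range(-m, 0):
            pts.append((k, pre_level + pre_slope * k))
        for i, k in enumerate(range(1, m + 1)):
            pts.append((k, post_level + post_slope * i))
        if noise is not None:
            pts = [(k, v + n) for (k, v), n in zip(pts, noise)]
        return pts

    def test_flat_series_has_zero_level_change(self):
        res = interrupted_time_series(self._series(100.0, 100.0))
        assert res.level_change == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_step_is_recovered_exactly(self):
        res = interrupted_time_series(self._series(100.0, 120.0))
        assert res.level_change == pytest.approx(20.0, abs=1e-8)
        assert res.pre_slope == pytest.approx(0.0, abs=1e-9)
        assert res.post_slope == pytest.approx(0.0, abs=1e-9)

    def test_distinct_segment_slopes_are_recovered(self):
        res = interrupted_time_series(
            self._series(100.0, 130.0, pre_slope=2.0, post_slope=-1.0, m=8))
        assert res.pre_slope == pytest.approx(2.0, abs=1e-8)
        assert res.post_slope == pytest.approx(-1.0, abs=1e-8)

    def test_short_segment_is_an_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            interrupted_time_series([(-2, 1.0), (-1, 1.0), (1, 2.0), (2, 2.0), (3, 2.0)])

    def test_period_zero_is_rejected(self):
        pts = self._series(1.0, 2.0) + [(0, 1.5)]
        with pytest.raises(ValueError, match="period 0"):
            interrupted_time_series(pts)

    def test_nan_periods_are_dropped(self):
        pts = self._series(100.0, 120.0, m=6)
        pts[0] = (pts[0][0], float("nan"))
        res = interrupted_time_series(pts)
        assert res.n_pre == 5 and res.n_post == 6


class TestNullCalibration:
    """Empirical type-I error of each test at alpha = 0.05 under the null."""

    def test_rank_and_paired_and_t_tests_are_calibrated(self, rng):
        reps = 1000
        rejections = {"rank": 0, "t": 0, "wilcoxon": 0}
        for _ in range(reps):
            a = rng.normal(120, 20, 25)
            b = rng.normal(120, 20, 25)
            if compare_unpaired(a, b, "rank").p_value < 0.05:
                rejections["rank"] += 1
            if compare_unpaired(a, b, "t").p_value < 0.05:
                rejections["t"] += 1
            if compare_paired(a, a + rng.normal(0, 5, 25)).p_value < 0.05:
                rejections["wilcoxon"] += 1
        for name, count in rejections.items():
            assert 0.03 <= count / reps <= 0.07, name
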