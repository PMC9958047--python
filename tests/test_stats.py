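import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f_oneway, levene as scipy_levene

from thermolegacy import stats
from thermolegacy.stats import (anova_oneway, compare_models, growth_rate,
                                levene_test, ols_regress, segmented_regress,
                                variability_summary)


class TestOls:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = ols_regress(x, 2.0 + 3.0 * x)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(2.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_regress([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_type_one_error_rate(self):
        # frozen from a 500-seed null simulation: empirical alpha 0.044
        rej = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            if ols_regress(rng.normal(size=1000),
                           rng.normal(size=1000)).p < 0.05:
                rej += 1
        assert abs(rej / 500 - 0.05) <= 0.02

    def test_matches_scipy_f_and_p(self):
        from scipy.stats import linregress
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 40)
        y = 1 + 0.5 * x + rng.normal(0, 1, 40)
        res = ols_regress(x, y)
        ref = linregress(x, y)
        assert res.slope == pytest.approx(ref.slope)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestCompareModels:
    @staticmethod
    def _frame(seed, n=14, signal=True):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"MAT": rng.uniform(12, 30, n),
                           "pH": rng.normal(8, 0.2, n),
                           "salinity": rng.normal(38, 2, n)})
        df["y"] = (5 + 2 * df.MAT if signal else 0) + rng.normal(0, 1, n)
        return df

    def test_eight_models_and_df_structure(self):
        # n = 14 transect layout: residual df 13 intercept-only, 12 for one
        # covariate, 11 for two, 10 for the full model
        ladder = compare_models(self._frame(0), "y")
        assert len(ladder) == 8
        by_terms = {m.terms: m for m in ladder}
        assert by_terms[()].df == (1, 13)
        assert by_terms[("MAT",)].df == (1, 12)
        assert by_terms[("MAT", "pH")].df == (2, 11)
        assert by_terms[("MAT", "pH", "salinity")].df == (3, 10)

    def test_mat_driven_response_selects_mat_only(self):
        # frozen from a 200-seed oracle run: MAT-only wins 57% of ladders
        # (AIC admits a spurious extra covariate with prob ~0.157 each,
        # so the theoretical ceiling is ~0.6, not higher)
        wins = sum(
            [m for m in compare_models(self._frame(seed), "y") if m.best
             ][0].terms == ("MAT",)
            for seed in range(200))
        assert wins / 200 >= 0.45

    def test_noise_response_favours_intercept(self):
        # intercept-only is the plurality winner on pure noise (49% frozen)
        counts = {}
        for seed in range(200):
            best = [m for m in compare_models(
                self._frame(seed, signal=False), "y") if m.best][0]
            counts[best.terms] = counts.get(best.terms, 0) + 1
        assert max(counts, key=counts.get) == ()

    def test_useless_covariate_aic_increment(self):
        # E[AIC_big - AIC_small] -> 2 - E[chi2_1] = 1 at large n
        incs = []
        for seed in range(200):
            df = self._frame(seed, n=2000)
            ladder = {m.terms: m.aic for m in compare_models(df, "y")}
            incs.append(ladder[("MAT", "pH")] - ladder[("MAT",)])
        assert np.mean(incs) == pytest.approx(1.0, abs=0.35)

    def test_matches_r_style_aic_convention(self):
        # AIC = n*log(2*pi*RSS/n) + n + 2*(p+1), checked by hand
        x = np.arange(10.0)
        y = np.array([1.1, 2.3, 2.8, 4.5, 4.9, 6.2, 7.1, 7.8, 9.3, 9.9])
        res = ols_regress(x, y)
        resid = y - (res.intercept + res.slope * x)
        rss = float(resid @ resid)
        expect = 10 * (np.log(2 * np.pi) + np.log(rss / 10) + 1) + 2 * 3
        assert res.aic == pytest.approx(expect, rel=1e-12)


class TestSegmented:
    @staticmethod
    def _piecewise(x, bp=27.7, b0=10.0, s1=0.45, s2=6.48):
        return b0 + s1 * x + (s2 - s1) * np.maximum(x - bp, 0.0)

    def test_exact_recovery_zero_noise(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(-1.4, 29.5, 150))
        fit = segmented_regress(x, self._piecewise(x))
        assert fit.breakpoint == pytest.approx(27.7, abs=1e-4)
        assert fit.slope_before == pytest.approx(0.45, abs=1e-6)
        assert fit.slope_after == pytest.approx(6.48, abs=1e-6)
        assert fit.p < 1e-6

    def test_rss_never_exceeds_linear(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.sort(rng.uniform(0, 30, 40))
            y = rng.normal(size=40)
            seg = segmented_regress(x, y)
            lin = ols_regress(x, y)
            assert seg.rss <= lin.rss + 1e-9

    def test_null_keeps_improvement_insignificant(self):
        # frozen from a 200-seed linear-truth run: rejection rate 9%
        rej = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.sort(rng.uniform(0, 30, 80))
            y = 1 + 0.5 * x + rng.normal(0, 1, 80)
            if segmented_regress(x, y).p <= 0.05:
                rej += 1
        assert rej / 200 <= 0.15

    def test_too_few_points_per_segment(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7])
        with pytest.raises(ValueError):
            segmented_regress(x[:4], x[:4])
        # 7 points but no candidate leaves 3 on each side of the percentile
        # window -> either a valid interior fit or a clean error
        fit = segmented_regress(x, 2 * x)
        assert x.min() < fit.breakpoint < x.max()

    def test_continuity_at_breakpoint(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 30, 60))
        y = self._piecewise(x, bp=15.0) + rng.normal(0, 0.3, 60)
        fit = segmented_regress(x, y)
        left = fit.intercept + fit.slope_before * fit.breakpoint
        right = (fit.intercept + fit.slope_before * fit.breakpoint
                 + (fit.slope_after - fit.slope_before) * 0.0)
        assert left == pytest.approx(right)


class TestLevene:
    def test_identical_groups_zero(self):
        g = [1.0, 2.0, 3.0]
        f, df, p = levene_test([g, g, g])
        assert f == 0.0
        assert df == (2, 6)

    def test_matches_scipy_brown_forsythe(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, s, 50) for s in (1.0, 2.0, 3.0)]
        f, df, p = levene_test(groups)
        ref = scipy_levene(*groups, center="median")
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_power_at_sd_ratio_three(self):
        # frozen power simulation: rejection in 200/200 runs
        rej = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            f, _, p = levene_test([rng.normal(0, 1, 1000),
                                   rng.normal(0, 3, 1000)])
            rej += p < 0.05
        assert rej / 200 >= 0.99

    def test_constant_group_with_median_center(self):
        f, df, p = levene_test([[5.0, 5.0, 5.0], [1.0, 2.0, 9.0]])
        assert np.isfinite(f)

    def test_center_mean_differs_on_skewed_data(self):
        rng = np.random.default_rng(2)
        groups = [rng.lognormal(0, 1, 200) for _ in range(2)]
        f_med, _, _ = levene_test(groups, center="median")
        f_mean, _, _ = levene_test(groups, center="mean")
        assert f_med != pytest.approx(f_mean)


class TestAnova:
    def test_identical_groups(self):
        f, df, p = anova_oneway([[1.0, 2.0], [1.0, 2.0]])
        assert f == 0.0

    def test_df_for_three_by_three_layout(self):
        f, df, p = anova_oneway([[1.0, 2, 3], [2.0, 3, 4], [3.0, 4, 5]])
        assert df == (2, 6)

    def test_hand_computed_table(self):
        # groups (1,2,3), (2,3,4), (6,7,8): SSB = 42, SSW = 6, F = 21
        groups = [[1.0, 2, 3], [2.0, 3, 4], [6.0, 7, 8]]
        f, df, p = anova_oneway(groups)
        assert f == pytest.approx(21.0, abs=1e-10)
        ref = f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [1.0, 2.0]])


class TestVariability:
    def test_constant_series(self):
        s = variability_summary([25.0] * 100)
        assert s.delta_t == 0.0
        assert s.bin_freq[0] == 100.0
        assert s.label == "LTV"

    def test_uniform_series_analytic_bins(self):
        # uniform on [22, 34): closed-form interval masses
        t = np.linspace(22.0, 34.0, 1_200_001)[:-1]
        s = variability_summary(t)
        assert s.bin_freq[0] == pytest.approx(100 * 6 / 12, abs=0.01)
        assert s.bin_freq[1] == pytest.approx(100 * 3 / 12, abs=0.01)
        assert s.bin_freq[2] == pytest.approx(100 * 3 / 12, abs=0.01)

    @given(st.lists(st.floats(0, 40), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_bins_always_sum_to_100(self, values):
        s = variability_summary(values)
        assert sum(s.bin_freq) == pytest.approx(100.0, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            variability_summary([])


class TestGrowth:
    def test_flat_low_od_is_no_growth(self):
        res = growth_rate(np.arange(10.0), np.full(10, 0.1))
        assert not res.grew
        assert res.rate is None

    def test_exact_exponential_rate(self):
        t = np.arange(0.0, 10.0, 0.5)
        res = growth_rate(t, 0.2 * np.exp(0.3 * t))
        assert res.grew
        assert res.rate == pytest.approx(0.3, rel=1e-9)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            growth_rate([0.0, 1, 2], [0.1, -0.1, 0.2])

    def test_logistic_recovery_within_ten_percent(self):
        from thermolegacy import simgen
        from thermolegacy.simgen import GenConfig
        for seed in range(20):
            frame = simgen.gen_growth_curves("HTV", 30.0,
                                             GenConfig(seed=seed),
                                             noise_sd=0.005)
            truth = frame.attrs["true_rate"]
            rep = frame[frame.replicate == 0]
            res = growth_rate(rep["time_h"].to_numpy(),
                              rep["od"].to_numpy())
            assert res.grew
            assert res.rate == pytest.approx(truth, rel=0.10)
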