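import numpy as np
import pandas as pd
import pytest

from thermolegacy import simgen, stats
from thermolegacy.simgen import (GenConfig, SiteTruth, gen_assay_plate,
                                 gen_growth_curves, gen_melting_curve,
                                 gen_site_dataset, gen_temperature_log,
                                 gen_toy_network)


class TestConfig:
    def test_invalid_relation(self):
        with pytest.raises(ValueError):
            GenConfig(relation="cubic")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            GenConfig(noise_sd=-1.0)

    def test_breakpoint_outside_range_rejected(self):
        with pytest.raises(ValueError, match="breakpoint"):
            GenConfig(relation="piecewise", breakpoint=40.0,
                      mat_range=(0.0, 30.0))


class TestSites:
    def test_noiseless_linear_identity(self):
        cfg = GenConfig(seed=1, n_sites=30, slope_before=1.3, intercept=5.0)
        sites = gen_site_dataset(cfg)
        mat = np.array([s.MAT for s in sites])
        y = np.array([s.topt_true for s in sites])
        res = stats.ols_regress(mat, y)
        assert res.slope == pytest.approx(1.3, abs=1e-9)
        assert res.intercept == pytest.approx(5.0, abs=1e-9)

    def test_piecewise_breakpoint_recovered(self):
        cfg = GenConfig(seed=2, n_sites=200, relation="piecewise",
                        slope_before=0.45, slope_after=6.48, breakpoint=27.7)
        sites = gen_site_dataset(cfg)
        mat = np.array([s.MAT for s in sites])
        y = np.array([s.topt_true for s in sites])
        fit = stats.segmented_regress(mat, y)
        assert fit.breakpoint == pytest.approx(27.7, abs=0.05)

    def test_breakpoint_recovery_bias_experiment(self):
        # frozen Monte-Carlo oracle (100 seeds, n=500, noise SD 1):
        # mean |error| 0.056, max 0.24 -> bound 0.15 on the mean
        errs = []
        for seed in range(100):
            cfg = GenConfig(seed=seed, n_sites=500, relation="piecewise",
                            slope_before=0.45, slope_after=6.48,
                            breakpoint=27.7, noise_sd=1.0)
            sites = gen_site_dataset(cfg)
            mat = np.array([s.MAT for s in sites])
            y = np.array([s.topt_true for s in sites])
            errs.append(abs(stats.segmented_regress(mat, y).breakpoint - 27.7))
        assert np.mean(errs) <= 0.15

    def test_determinism(self):
        cfg = GenConfig(seed=11, n_sites=20, noise_sd=1.0)
        assert gen_site_dataset(cfg) == gen_site_dataset(cfg)

    def test_covariates_independent_of_truth(self):
        cfg = GenConfig(seed=3, n_sites=400, noise_sd=0.0)
        frame = simgen.sites_to_frame(gen_site_dataset(cfg))
        r_ph = stats.ols_regress(frame["pH"], frame["topt_true"])
        assert r_ph.p > 0.01


class TestAssay:
    SITE = SiteTruth("S0", 20.0, 8.0, 38.0, topt_true=55.0, td_true=60.0)

    def test_empty_temperature_list_rejected(self):
        with pytest.raises(ValueError):
            gen_assay_plate(self.SITE, [], GenConfig())

    def test_three_replicates_per_temperature(self):
        plate = gen_assay_plate(self.SITE, [20.0, 40.0], GenConfig(),
                                duration_min=10, interval_s=60)
        assert set(plate["replicate"]) == {0, 1, 2}

    def test_true_slope_peaks_at_topt(self):
        temps = np.arange(10.0, 80.0, 5.0)
        plate = gen_assay_plate(self.SITE, temps, GenConfig(),
                                duration_min=10, interval_s=60)
        slopes = plate.attrs["true_slopes"]
        assert max(slopes, key=slopes.get) == 55.0

    def test_zero_mean_noise(self):
        # residual mean over >=1e4 draws within 3 SE of zero
        cfg = GenConfig(seed=5, assay_noise_sd=0.01)
        plate = gen_assay_plate(self.SITE, np.arange(10.0, 70.0, 6.0), cfg,
                                duration_min=180, interval_s=30)
        resid = []
        for (temp, _rep), grp in plate.groupby(["temperature_C", "replicate"]):
            slope = plate.attrs["true_slopes"][temp]
            resid.append(grp["absorbance"].to_numpy()
                         - (0.05 + slope * grp["time_min"].to_numpy()))
        resid = np.concatenate(resid)
        assert resid.size >= 10_000
        assert abs(resid.mean()) <= 3 * 0.01 / np.sqrt(resid.size)


class TestMelting:
    def test_out_of_range_flagged(self):
        m = gen_melting_curve(120.0, GenConfig())
        assert m.out_of_range

    def test_in_range_not_flagged(self):
        assert not gen_melting_curve(50.0, GenConfig()).out_of_range

    def test_grid_matches_ramp(self):
        m = gen_melting_curve(50.0, GenConfig(), t_start=4.0, t_stop=95.0,
                              n_points=183)
        assert m.temperature[0] == 4.0
        assert m.temperature[-1] == 95.0
        assert m.temperature.size == 183


class TestToyNetwork:
    def test_invalid_planted_ecut(self):
        with pytest.raises(ValueError):
            gen_toy_network(5, -7.0, GenConfig())

    def test_minimum_bodies(self):
        with pytest.raises(ValueError):
            gen_toy_network(1, -3.0, GenConfig())

    def test_truth_exposed(self):
        net = gen_toy_network(6, -2.2, GenConfig())
        assert net.meta["planted_ecut"] == -2.2


class TestLogger:
    def test_delta_t_ordering(self):
        cfg = GenConfig(seed=0)
        dts = {c: np.ptp(gen_temperature_log(c, 18, cfg)["temperature_C"])
               for c in ("HTV", "ITV", "LTV")}
        assert dts["HTV"] > dts["ITV"] > dts["LTV"]

    def test_means_within_2p5_degrees(self):
        cfg = GenConfig(seed=0)
        means = [gen_temperature_log(c, 18, cfg)["temperature_C"].mean()
                 for c in ("HTV", "ITV", "LTV")]
        assert max(means) - min(means) <= 2.5

    def test_zero_amplitude_zero_delta(self):
        log = gen_temperature_log("HTV", 6, GenConfig(), amplitude_scale=0.0,
                                  noise_sd=0.0)
        s = stats.variability_summary(log["temperature_C"].to_numpy())
        assert s.delta_t == 0.0

    def test_half_hour_sampling(self):
        log = gen_temperature_log("LTV", 18, GenConfig())
        assert np.allclose(np.diff(log["time_h"]), 0.5)
        # ~52,700-point order of magnitude over 18 months at 2/h
        assert 24_000 <= len(log) <= 28_000


class TestGrowth:
    def test_no_growth_below_threshold(self):
        # 10 degC is far below every class optimum -> capped near OD 0.1
        frame = gen_growth_curves("LTV", 10.0, GenConfig())
        assert not frame.attrs["grew_truth"]
        rep = frame[frame.replicate == 0]
        res = stats.growth_rate(rep["time_h"].to_numpy(),
                                rep["od"].to_numpy())
        assert not res.grew

    def test_noiseless_logistic_rate_recovery(self):
        frame = gen_growth_curves("HTV", 33.0, GenConfig(), noise_sd=0.0,
                                  interval_h=1.0)
        rep = frame[frame.replicate == 0]
        res = stats.growth_rate(rep["time_h"].to_numpy(),
                                rep["od"].to_numpy())
        assert res.rate == pytest.approx(frame.attrs["true_rate"], rel=0.05)

    def test_anova_power_htv_vs_ltv_at_40(self):
        # frozen power simulation (100 seeds): rejection in every run
        rej = 0
        for seed in range(100):
            cfg = GenConfig(seed=seed)
            gs = []
            for c in ("HTV", "LTV"):
                frame = gen_growth_curves(c, 40.0, cfg, noise_sd=0.01)
                gs.append([stats.growth_rate(g["time_h"].to_numpy(),
                                             g["od"].to_numpy()).rate
                           for _, g in frame.groupby("replicate")])
            _, _, p = stats.anova_oneway(gs)
            rej += p < 0.05
        assert rej / 100 >= 0.9


class TestDeterminismEverywhere:
    def test_identical_config_identical_frames(self):
        cfg = GenConfig(seed=42, assay_noise_sd=0.01, melt_noise_frac=0.02)
        site = SiteTruth("S1", 22.0, 8.0, 38.0, topt_true=45.0, td_true=52.0)
        p1 = gen_assay_plate(site, [20.0, 40.0], cfg, duration_min=10,
                             interval_s=60)
        p2 = gen_assay_plate(site, [20.0, 40.0], cfg, duration_min=10,
                             interval_s=60)
        pd.testing.assert_frame_equal(p1, p2)
        m1 = gen_melting_curve(50.0, cfg)
        m2 = gen_melting_curve(50.0, cfg)
        assert np.array_equal(m1.signal, m2.signal)
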