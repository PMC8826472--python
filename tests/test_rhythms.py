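"""Cosinor fits, daily profiles and non-parametric circadian metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circstrain import rhythms
from circstrain.rhythms import (MetricError, daily_profile, fit_cosinor,
                                group_profile, interdaily_stability,
                                intradaily_variability, log_light_ra, m10_l5,
                                relative_amplitude)

from conftest import make_series


class TestCosinor:
    def test_exact_recovery_of_pure_cosinusoid(self):
        t = np.arange(7 * 144) * (10 / 60.0)
        x = 5.0 + 3.0 * np.cos(2 * np.pi * (t - 14.0) / 24.0)
        fit = fit_cosinor(make_series(x))
        assert fit.mesor == pytest.approx(5.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(14.0, abs=1e-9)
        assert fit.goodness == pytest.approx(1.0, abs=1e-12)

    def test_constant_series(self):
        fit = fit_cosinor(make_series(np.full(288, 7.0)))
        assert fit.mesor == pytest.approx(7.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.goodness == 0.0

    def test_noisy_simulated_series_recovers_parameters(self):
        # generator ground truth: mesor 105, amplitude 95, peak at 14 h
        from circstrain.synthgen import SeriesParams, simulate_epoch_series
        p = SeriesParams(mode="cosine", noise_cv=0.3, phase_jitter_sd_h=0.0,
                         frag_switch_prob=0.0)
        fit = fit_cosinor(simulate_epoch_series(p, 42))
        assert fit.mesor == pytest.approx(105.0, rel=0.05)
        assert fit.amplitude == pytest.approx(95.0, rel=0.05)
        assert fit.acrophase_h == pytest.approx(14.0, abs=0.5)

    def test_acrophase_respects_series_start_clock_time(self):
        t = np.arange(3 * 144) * (10 / 60.0)
        x = 10.0 + 4.0 * np.cos(2 * np.pi * ((t + 6.0) - 20.0) / 24.0)
        fit = fit_cosinor(make_series(x, start="2019-04-01 06:00:00"))
        assert fit.acrophase_h == pytest.approx(20.0, abs=1e-6)

    def test_amplitude_unbiased_under_additive_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(7 * 144) * (10 / 60.0)
        clean = 50.0 + 10.0 * np.cos(2 * np.pi * (t - 12.0) / 24.0)
        amps = []
        for _ in range(200):
            fit = fit_cosinor(make_series(clean + rng.normal(0, 5.0, clean.size)))
            amps.append(fit.amplitude)
        se = np.std(amps, ddof=1) / math.sqrt(len(amps))
        assert abs(np.mean(amps) - 10.0) < 2 * se

    def test_all_missing_channel_errors(self):
        with pytest.raises(MetricError):
            fit_cosinor(make_series(np.full(288, np.nan)))


class TestProfiles:
    def test_identical_days_profile_equals_single_day(self, tiled_week):
        prof = daily_profile(tiled_week, "activity", "mean")
        np.testing.assert_allclose(prof.values, tiled_week.activity[:144])
        assert np.all(prof.n_days_contributing == 7)

    @pytest.mark.parametrize("stat,days,expected", [
        ("mean", (2.0, 4.0, 6.0), 4.0),
        ("median", (1.0, 1.0, 100.0), 1.0),
    ])
    def test_bin_statistics(self, stat, days, expected):
        x = np.concatenate([np.full(144, v) for v in days])
        prof = daily_profile(make_series(x), "activity", stat)
        assert prof.values[0] == pytest.approx(expected)

    def test_group_profile_single_subject_identity(self, tiled_week):
        prof = daily_profile(tiled_week, "activity", "mean")
        gp = group_profile([prof], "median")
        np.testing.assert_allclose(gp.values, prof.values)

    def test_group_profile_mean_of_constants(self):
        p1 = daily_profile(make_series(np.full(288, 10.0)), "activity", "mean")
        p2 = daily_profile(make_series(np.full(288, 30.0)), "activity", "mean")
        gp = group_profile([p1, p2], "mean")
        np.testing.assert_allclose(gp.values, 20.0)
        assert gp.sem is not None

    def test_group_median_matches_naive_per_bin_recompute(self):
        rng = np.random.default_rng(8)
        series = [make_series(rng.gamma(2.0, 20.0, 3 * 144)) for _ in range(3)]
        profs = [daily_profile(s, "activity", "mean") for s in series]
        gp = group_profile(profs, "median")
        stacked = np.vstack([p.values for p in profs])
        for b in range(0, 144, 7):
            assert gp.values[b] == pytest.approx(np.median(stacked[:, b]))

    def test_mixed_epoch_sizes_rejected(self):
        p1 = daily_profile(make_series(np.ones(144), epoch_min=10), "activity")
        p2 = daily_profile(make_series(np.ones(48), epoch_min=30), "activity")
        with pytest.raises(ValueError):
            group_profile([p1, p2])


class TestIS:
    def test_perfect_repetition_attains_one(self, tiled_week):
        assert interdaily_stability(tiled_week) == pytest.approx(1.0, abs=1e-12)

    def test_iid_noise_gives_one_over_n_days(self):
        # Monte-Carlo oracle: for iid noise the across-day bin means explain
        # ~1/n_days of the variance
        rng = np.random.default_rng(123)
        vals = [interdaily_stability(make_series(rng.gamma(2.0, 10.0, 1008)))
                for _ in range(200)]
        assert np.mean(vals) == pytest.approx(1.0 / 7.0, abs=0.05)

    def test_constant_series_errors(self):
        with pytest.raises(MetricError):
            interdaily_stability(make_series(np.full(1008, 3.0)))

    def test_single_day_errors(self):
        with pytest.raises(MetricError):
            interdaily_stability(make_series(np.arange(144, dtype=float) + 1))


class TestIV:
    def test_white_noise_near_two(self):
        rng = np.random.default_rng(7)
        vals = [intradaily_variability(make_series(
            np.abs(rng.normal(100, 10, 1008)))) for _ in range(50)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.05)

    def test_pure_sinusoid_closed_form(self, seven_day_sinusoid):
        iv = intradaily_variability(seven_day_sinusoid)
        expected = 2.0 * (1.0 - math.cos(2 * math.pi / 144))
        assert iv == pytest.approx(expected, rel=0.01)
        assert round(iv, 1) == 0.0

    def test_constant_series_errors(self):
        with pytest.raises(MetricError):
            intradaily_variability(make_series(np.full(1008, 5.0)))

    def test_missing_pairs_excluded(self):
        x = np.array([1.0, 2.0, np.nan] * 400)
        # no consecutive non-missing pairs crossing the gap: only (1,2) pairs
        iv = intradaily_variability(make_series(x), min_coverage=0.5)
        assert np.isfinite(iv)
        # every retained successive difference is exactly 1
        n = 400 + 1
        sst = ((np.array([1.0, 2.0] * 400) - 1.5) ** 2).sum()
        assert iv == pytest.approx(n * 400 * 1.0 / ((n - 1) * sst))


class TestM10L5:
    def test_constant_profile(self):
        prof = daily_profile(make_series(np.full(1008, 5.0)), "activity", "mean")
        m10, _, l5, _ = m10_l5(prof)
        assert m10 == l5 == pytest.approx(5.0)

    def test_square_wave_day(self):
        x = np.zeros(144)
        x[48:120] = 100.0     # 08:00-20:00 high block
        prof = daily_profile(make_series(np.tile(x, 7)), "activity", "mean")
        m10, m10_on, l5, l5_on = m10_l5(prof)
        assert m10 == pytest.approx(100.0)
        assert 8.0 <= m10_on <= 10.0
        assert l5 == pytest.approx(0.0)

    def test_l5_wraps_across_midnight(self):
        x = np.full(144, 50.0)
        x[132:] = 0.0    # 22:00-24:00
        x[:18] = 0.0     # 00:00-03:00
        prof = daily_profile(make_series(np.tile(x, 7)), "activity", "mean")
        _, _, l5, l5_on = m10_l5(prof)
        assert l5 == pytest.approx(0.0)
        assert l5_on == pytest.approx(22.0)

    def test_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            vals = rng.gamma(1.5, 40.0, 144)
            prof = rhythms.DailyProfile("activity", 10, vals, "mean",
                                        np.full(144, 7))
            m10, m10_on, l5, l5_on = m10_l5(prof)
            ext = np.concatenate([vals, vals])
            means10 = np.array([ext[i:i + 60].mean() for i in range(144)])
            means5 = np.array([ext[i:i + 30].mean() for i in range(144)])
            assert m10 == pytest.approx(means10.max(), rel=1e-12)
            assert l5 == pytest.approx(means5.min(), rel=1e-12)
            assert m10_on == pytest.approx(int(np.argmax(means10)) / 6.0)
            assert l5_on == pytest.approx(int(np.argmin(means5)) / 6.0)

    def test_fully_undefined_profile_errors(self):
        prof = rhythms.DailyProfile("activity", 10, np.full(144, np.nan),
                                    "mean", np.zeros(144, dtype=int))
        with pytest.raises(MetricError):
            m10_l5(prof)


class TestAmplitudes:
    @pytest.mark.parametrize("m10,l5,expected", [
        (100.0, 0.0, 1.0), (50.0, 50.0, 0.0), (300.0, 100.0, 0.5)])
    def test_relative_amplitude(self, m10, l5, expected):
        assert relative_amplitude(m10, l5) == pytest.approx(expected)

    def test_relative_amplitude_zero_sum_errors(self):
        with pytest.raises(MetricError):
            relative_amplitude(0.0, 0.0)

    @pytest.mark.parametrize("m10,l5,expected", [
        (990.0, 0.0, 0.5), (40.0, 40.0, 0.0), (90.0, 0.0, 1.0 / 3.0)])
    def test_log_light_ra(self, m10, l5, expected):
        assert log_light_ra(m10, l5) == pytest.approx(expected)


class TestInvarianceProperties:
    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(0.0, 500.0),
           seed=st.integers(0, 10_000))
    def test_is_iv_affine_invariant(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 10.0, 2 * 144) + 1.0
        a = make_series(x)
        b = make_series(scale * x + offset)
        assert interdaily_stability(b) == pytest.approx(
            interdaily_stability(a), rel=1e-9)
        assert intradaily_variability(b) == pytest.approx(
            intradaily_variability(a), rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_is_bounded_and_ra_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        s = make_series(rng.gamma(2.0, 10.0, 7 * 144) + 0.1)
        r = rhythms.npcra(s, "activity")
        assert 0.0 <= r.IS <= 1.0 + 1e-9
        assert r.IV >= 0.0
        assert r.M10 >= r.L5 >= 0.0
        assert 0.0 <= r.RA <= 1.0
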