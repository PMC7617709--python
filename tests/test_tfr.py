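import numpy as np
import pytest

from tmseegkit.tfr import (BandROI, DEFAULT_ROIS, TFRPower, WaveletSpec,
                           change_score_regression, db_normalize,
                           morlet_decompose, roi_power, three_way_rm_anova,
                           wilcoxon_posthoc)


class TestWaveletSpec:
    def test_frequency_grid_closed_form(self):
        spec = WaveletSpec()
        f = spec.freqs
        assert f[0] == pytest.approx(3.0)
        assert f[-1] == pytest.approx(70.0)
        assert len(f) == 30
        j = np.arange(30)
        assert np.allclose(f, 3.0 * (70.0 / 3.0) ** (j / 29.0), rtol=1e-12)

    def test_cycles_endpoints(self):
        spec = WaveletSpec()
        assert spec.cycles[0] == pytest.approx(3.0)
        assert spec.cycles[-1] == pytest.approx(10.0)
        assert np.all(np.diff(spec.cycles) > 0)


class TestMorletDecompose:
    def test_pure_sinusoid_power_peak(self, epochs_factory):
        srate = 500.0
        t = np.arange(int(srate)) / srate - 0.5
        sig = np.sin(2 * np.pi * 10.0 * t)
        ep = epochs_factory(np.tile(sig, (2, 1))[:, :, None], srate=srate,
                            t0_index=int(srate) // 2)
        tfr = morlet_decompose(ep, bandpass=None)
        mean_pow = tfr.power.mean(axis=(1, 2))
        peak = tfr.freqs[np.argmax(mean_pow)]
        grid_nearest = tfr.freqs[np.argmin(np.abs(tfr.freqs - 10.0))]
        assert peak == pytest.approx(grid_nearest)

    def test_white_noise_db_baseline_near_zero(self, epochs_factory, rng):
        srate = 500.0
        ep = epochs_factory(rng.standard_normal((2, 500, 12)), srate=srate,
                            t0_index=250)
        tfr = db_normalize(morlet_decompose(ep, bandpass=None),
                           (-400.0, -200.0))
        # mean dB over the baseline window is ~0 up to the Jensen gap
        # (mean of log vs log of mean over the window)
        mask = tfr.time_mask(-400.0, -200.0)
        assert abs(tfr.power[:, mask].mean()) < 0.5
        # and any window of a stationary signal stays near 0 dB
        post = tfr.time_mask(100.0, 300.0)
        assert abs(tfr.power[:, post].mean()) < 2.0

    def test_above_nyquist_rejected(self, epochs_factory):
        ep = epochs_factory(np.zeros((2, 300, 1)), srate=120.0)
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_decompose(ep)

    def test_trial_order_invariance(self, epochs_factory, rng):
        x = rng.standard_normal((2, 400, 6))
        srate = 500.0
        a = morlet_decompose(epochs_factory(x, srate=srate), concat=False,
                             bandpass=None)
        b = morlet_decompose(epochs_factory(x[:, :, ::-1], srate=srate),
                             concat=False, bandpass=None)
        assert np.allclose(a.power, b.power, atol=1e-10)

    def test_db_invariant_to_global_scaling(self, epochs_factory, rng):
        x = rng.standard_normal((2, 500, 4))
        srate = 500.0
        a = db_normalize(morlet_decompose(epochs_factory(x, srate=srate)),
                         (-400.0, -200.0))
        b = db_normalize(
            morlet_decompose(epochs_factory(7.5 * x, srate=srate)),
            (-400.0, -200.0))
        assert np.allclose(a.power, b.power, atol=1e-9)

    def test_20ms_time_grid(self, epochs_factory, rng):
        ep = epochs_factory(rng.standard_normal((2, 500, 2)), srate=500.0)
        tfr = morlet_decompose(ep)
        assert np.allclose(np.diff(tfr.times_ms), 20.0)


class TestDbNormalize:
    def _flat_tfr(self, value=4.0):
        freqs = np.array([5.0, 10.0])
        times = np.arange(-500.0, 500.0, 20.0)
        power = np.full((2, times.size, 3), value)
        return TFRPower(power, freqs, times, 20.0)

    def test_power_equal_baseline_gives_zero_db(self):
        out = db_normalize(self._flat_tfr(), (-400.0, -200.0))
        assert np.allclose(out.power, 0.0)

    def test_log_identities(self):
        tfr = self._flat_tfr(1.0)
        p = tfr.power.copy()
        mask = tfr.time_mask(0.0, 200.0)
        p[:, mask] = 10.0
        out = db_normalize(TFRPower(p, tfr.freqs, tfr.times_ms, 20.0),
                           (-400.0, -200.0))
        assert np.allclose(out.power[:, mask], 10.0)
        p[:, mask] = 0.1
        out = db_normalize(TFRPower(p, tfr.freqs, tfr.times_ms, 20.0),
                           (-400.0, -200.0))
        assert np.allclose(out.power[:, mask], -10.0)

    def test_injected_ratio_recovered(self, epochs_factory, rng):
        # burst with known power ratio r over the baseline level
        srate = 500.0
        n = 500
        t = (np.arange(n) - 250) / srate
        f0 = 20.0  # wavelet here is narrow (sigma_t ~ 50 ms)
        env = np.exp(-((t - 0.25) ** 2) / (2 * 0.1 ** 2))
        r = 9.0
        burst = (np.sqrt(r) * np.sin(2 * np.pi * f0 * t)[None, :, None]
                 * env[None, :, None])
        carrier = np.sin(2 * np.pi * f0 * t[None, :, None]
                         + rng.uniform(0, 2 * np.pi, (2, 1, 30)))
        ep = epochs_factory(carrier + burst, srate=srate)
        tfr = db_normalize(morlet_decompose(ep, bandpass=None),
                           (-400.0, -200.0))
        fm = tfr.freq_mask(18.0, 22.0)
        tm = tfr.time_mask(200.0, 300.0)
        got = tfr.power[np.ix_(fm, tm)].mean()
        # near the envelope peak the burst adds ~r times the carrier power
        assert got == pytest.approx(10 * np.log10(1 + r), abs=2.5)

    def test_zero_baseline_rejected(self):
        tfr = self._flat_tfr(0.0)
        with pytest.raises(ValueError, match="baseline"):
            db_normalize(tfr, (-400.0, -200.0))


class TestRoiPower:
    NAMES = ("AF3", "F3", "F1", "C1", "Cz", "C2", "FC1", "FCz", "FC2", "O1")

    def _tfr(self, fill):
        freqs = np.geomspace(3.0, 70.0, 30)
        times = np.arange(-500.0, 500.0, 20.0)
        power = np.full((30, times.size, len(self.NAMES)), fill)
        return TFRPower(power, freqs, times, 20.0, is_db=True)

    def test_uniform_field(self):
        tfr = self._tfr(3.25)
        for roi in DEFAULT_ROIS.values():
            assert roi_power(tfr, roi, self.NAMES) == pytest.approx(3.25)

    def test_theta_roi_excludes_10hz(self):
        tfr = self._tfr(0.0)
        p = tfr.power.copy()
        fi = np.argmin(np.abs(tfr.freqs - 10.0))
        p[fi] = 100.0
        tfr2 = TFRPower(p, tfr.freqs, tfr.times_ms, 20.0, is_db=True)
        assert roi_power(tfr2, DEFAULT_ROIS["theta"], self.NAMES) == 0.0

    def test_band_ordering_preserved(self, rng):
        tfr = self._tfr(0.0)
        p = tfr.power.copy()
        for band, level in [("beta", 2.0), ("gamma", 5.0)]:
            roi = DEFAULT_ROIS[band]
            fm = tfr.freq_mask(*roi.f_window_hz)
            tm = tfr.time_mask(*roi.t_window_ms)
            ci = [self.NAMES.index(e) for e in roi.electrodes]
            p[np.ix_(fm, tm, ci)] += level
        tfr2 = TFRPower(p, tfr.freqs, tfr.times_ms, 20.0, is_db=True)
        assert (roi_power(tfr2, DEFAULT_ROIS["gamma"], self.NAMES)
                > roi_power(tfr2, DEFAULT_ROIS["beta"], self.NAMES))

    def test_missing_electrode_rejected(self):
        tfr = self._tfr(0.0)
        roi = BandROI("x", (0.0, 40.0), (10.0, 20.0), ("F3", "Qz"))
        with pytest.raises(ValueError, match="Qz"):
            roi_power(tfr, roi, self.NAMES)

    def test_gamma_roi_starts_before_zero(self):
        assert DEFAULT_ROIS["gamma"].t_window_ms[0] == -20.0


class TestThreeWayAnova:
    def test_all_equal_f_zero(self):
        y = np.tile(np.arange(6.0)[:, None, None, None], (1, 2, 2, 2))
        table = three_way_rm_anova(y)
        assert np.allclose(table.F, 0.0)
        assert len(table) == 7

    def test_eta_bounded(self, rng):
        table = three_way_rm_anova(rng.standard_normal((8, 2, 2, 2)))
        assert ((table.eta_sq_g >= 0) & (table.eta_sq_g <= 1)).all()

    def test_incomplete_rejected(self, rng):
        y = rng.standard_normal((5, 2, 2, 2))
        y[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            three_way_rm_anova(y)


class TestWilcoxonPosthoc:
    def test_no_change_p_one(self):
        x = np.arange(8.0)
        _, p = wilcoxon_posthoc(x, x.copy())
        assert p == 1.0

    def test_direction_in_z_sign(self, rng):
        pre = rng.standard_normal(20)
        post = pre + 1.0
        z_up, _ = wilcoxon_posthoc(pre, post)
        z_down, _ = wilcoxon_posthoc(pre, pre - 1.0)
        assert z_up > 0 > z_down


class TestChangeScoreRegression:
    def test_exact_linear_equals_ls(self, rng):
        n = 24
        base = rng.standard_normal(n)
        cond = np.array(["active", "sham"] * (n // 2))
        code = np.where(cond == "active", 0.5, -0.5)
        change = 1.0 - 0.6 * (base - base.mean()) + 0.4 * (code - code.mean())
        fit = change_score_regression(base, base + change, cond)
        assert fit.params[0] == pytest.approx(1.0, abs=1e-8)
        assert fit.params[1] == pytest.approx(-0.6, abs=1e-8)
        assert fit.params[2] == pytest.approx(0.4, abs=1e-8)
        assert fit.params[3] == pytest.approx(0.0, abs=1e-8)
        assert fit.df_resid == n - 4

    def test_outlier_robustness_vs_ls(self, rng):
        n = 48
        base = rng.standard_normal(n)
        cond = np.array(["active", "sham"] * (n // 2))
        slope = -0.7
        change = slope * (base - base.mean()) + rng.normal(0, 0.15, n)
        post = base + change
        post[3] += 25.0
        fit = change_score_regression(base, post, cond)
        X = np.column_stack([np.ones(n), base - base.mean()])
        ls = np.linalg.lstsq(X, post - base, rcond=None)[0]
        assert abs(fit.params[1] - slope) < abs(ls[1] - slope)

    def test_negative_slope_recovered(self, rng):
        n = 24
        base = rng.standard_normal(n) * 2.0
        cond = np.array(["active"] * 12 + ["sham"] * 12)
        change = -0.5 * (base - base.mean()) + rng.normal(0, 0.3, n)
        fit = change_score_regression(base, base + change, cond)
        assert fit.params[1] < 0
        assert abs(fit.params[1] + 0.5) < 2 * fit.bse[1]

    def test_interaction_is_slope_difference(self, rng):
        n = 40
        base = rng.standard_normal(n)
        cond = np.array(["active", "sham"] * (n // 2))
        s_active, s_sham = -0.8, -0.2
        slopes = np.where(cond == "active", s_active, s_sham)
        change = slopes * (base - base.mean()) + rng.normal(0, 0.05, n)
        fit = change_score_regression(base, base + change, cond)
        assert fit.params[3] == pytest.approx(s_active - s_sham, abs=0.1)

    def test_requirements(self, rng):
        with pytest.raises(ValueError, match="8 observations"):
            change_score_regression([1.0] * 4, [1.0] * 4,
                                    ["active", "sham"] * 2)
        with pytest.raises(ValueError, match="2 levels"):
            change_score_regression(np.arange(10.0), np.arange(10.0),
                                    ["active"] * 10)
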