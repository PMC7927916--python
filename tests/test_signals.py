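import numpy as np
import pytest

from onoffstate.signals import (bipolar_reref, common_average_reference,
                                csd_fd, energy, fdr_correct, latency_fit,
                                muae, multitaper_psd, rf_summary, snr,
                                state_spectra, stouffer_combine,
                                _latency_model)


class TestReferencing:
    def test_car_identical_channels_zero(self):
        v = np.tile(np.sin(np.arange(100.0)), (4, 1))
        assert np.abs(common_average_reference(v)).max() == 0.0

    def test_car_mean_zero_and_idempotent(self, rng):
        v = rng.normal(size=(6, 200))
        out = common_average_reference(v)
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(common_average_reference(out), out,
                                   atol=1e-12)

    def test_bipolar_constant_zero_linear_constant(self):
        const = np.ones((5, 50))
        assert np.abs(bipolar_reref(const)).max() == 0.0
        ramp = np.arange(16.0)[:, None] * np.ones((16, 30))
        out = bipolar_reref(ramp)
        assert out.shape == (15, 30)
        np.testing.assert_allclose(out, -1.0)

    def test_energy(self):
        assert energy([2.0, 2.0, 2.0]) == 12.0
        assert energy(np.zeros(5)) == 0.0
        assert energy(3.0 * np.ones(4)) == 9.0 * energy(np.ones(4))


class TestCsd:
    def test_linear_profile_zero(self):
        phi = np.linspace(0, 10, 8)[:, None] * np.ones((8, 20))
        assert np.abs(csd_fd(phi)).max() < 1e-15

    def test_quadratic_exact(self):
        h = 150.0
        x = h * np.arange(9)
        phi = (x ** 2)[:, None] * np.ones((9, 5))
        out = csd_fd(phi, h)
        np.testing.assert_allclose(out, 2.0, rtol=1e-12)

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            csd_fd(np.ones((2, 10)))

    def test_dipole_localized(self):
        from onoffstate.synthetic import (GenConfig, build_joint_transitions,
                                          simulate_session)
        cfg = GenConfig(n_trials=2, channels_per_area=16, seed=2,
                        transitions={"attend_rf": build_joint_transitions()},
                        include_lfp=True, include_eye=False, msacc_rate=0.0)
        b = simulate_session(cfg)
        csd = np.mean([np.abs(csd_fd(tr)).mean(axis=1) for tr in b.lfp.data],
                      axis=0)
        # interior channel k corresponds to laminar contact k+1
        peak_contact = int(np.argmax(csd)) + 1
        assert abs(peak_contact - cfg.lfp_dipole_channel) <= 1


class TestMuae:
    def test_dc_passthrough(self):
        fs = 30000.0
        out = muae(np.full(3000, 2.0), fs)
        assert out[-100:].mean() == pytest.approx(2.0, rel=0.01)

    def test_rectified_tone_mean(self):
        # tone incommensurate with fs so sampling sweeps all phases and
        # the discrete rectified mean approaches 2A/pi
        fs = 30000.0
        t = np.arange(int(fs)) / fs
        a = 1.7
        out = muae(a * np.sin(2 * np.pi * 4873.0 * t), fs)
        assert out[-5000:].mean() == pytest.approx(2 * a / np.pi, rel=0.02)


class TestSnr:
    def make_trials(self, gain, rng, n_trials=20, fs=1000.0):
        n = 700
        x = rng.normal(1.0, 0.05, size=(n_trials, 2, n))
        # channel 0 gets an evoked bump 30..150 ms after onset (at 300 ms)
        t = np.arange(n) - 300
        bump = np.exp(-0.5 * ((t - 90) / 30.0) ** 2)
        x[:, 0] += gain * bump
        return x

    def test_flat_channel_excluded_strong_included(self, rng):
        x = self.make_trials(0.5, rng)
        vals, inc = snr(x, 1000.0, 300.0)
        assert inc[0]
        assert not inc[1]

    def test_boundary_not_strictly_greater(self):
        # Signal-Noise exactly 3 sigma must NOT be included
        x = np.zeros((4, 1, 700))
        vals, inc = snr(x + 1.0, 1000.0, 300.0)
        assert not inc[0]          # sigma=0 -> undefined, excluded


class TestLatency:
    def test_cumulative_gaussian_closed_form(self):
        from scipy.stats import norm
        fs = 1000.0
        mu, sig = 60.0, 8.0
        t = np.arange(-100, 200) / fs * 1000.0
        y = 1.0 * norm.cdf(t, mu, sig)
        out = latency_fit(y, fs, onset_ms=100.0)
        assert out.converged
        expected = mu + sig * norm.ppf(0.33)
        assert out.latency_ms == pytest.approx(expected, abs=1.0)

    def test_noiseless_parameter_recovery(self):
        fs = 1000.0
        t = np.arange(-100, 300) / fs * 1000.0
        true = dict(mu=60.0, sigma=8.0, alpha=0.02, c=0.6, d=0.8)
        y = _latency_model(t, **true)
        out = latency_fit(y, fs, onset_ms=100.0)
        assert out.converged
        for k in ("mu", "sigma", "alpha"):
            assert out.params[k] == pytest.approx(true[k], rel=0.01)

    def test_flat_trace_missing(self):
        out = latency_fit(np.ones(300), 1000.0, onset_ms=100.0)
        assert out.latency_ms is None


class TestSpectra:
    def test_tone_peak_at_60hz(self, rng):
        fs = 1000.0
        t = np.arange(512) / fs
        seg = np.sin(2 * np.pi * 60.0 * t) + 0.1 * rng.normal(size=512)
        f, psd = multitaper_psd(seg, fs)
        assert abs(f[np.argmax(psd)] - 60.0) < 4.0

    def test_padding_to_1024(self):
        f, psd = multitaper_psd(np.random.default_rng(0).normal(size=250),
                                1000.0, pad_to=1024)
        assert len(f) == 1024 // 2 + 1

    def test_state_conditioned_power_difference(self, rng):
        # 60 Hz present only during On epochs
        fs, w = 1000.0, 10.0
        paths, lfp = [], []
        for _ in range(12):
            T = 100
            p = np.zeros(T, int)
            p[30:70] = 1
            t = np.arange(int(T * w * fs / 1000.0)) / fs
            on = np.repeat(p, int(w * fs / 1000.0)).astype(float)
            sig = rng.normal(0, 0.5, size=len(t)) \
                + 2.0 * np.sin(2 * np.pi * 60.0 * t) * on
            paths.append(p)
            lfp.append(sig[None, :])
        out = state_spectra(lfp, paths, fs=fs, w_bin=w, min_epoch_ms=250.0)
        pc = out.percent_change["on_vs_off"][0]
        band = (out.freqs > 52) & (out.freqs < 68)
        rest = (out.freqs > 100) & (out.freqs < 180)
        assert pc[band].mean() > 100.0
        assert abs(pc[rest].mean()) < 50.0

    def test_epoch_shorter_than_min_skipped(self, rng):
        paths = [np.array([0] * 10 + [1] * 10 + [0] * 10)]  # 100 ms epochs
        lfp = [rng.normal(size=(1, 300))]
        with pytest.raises(ValueError, match="no qualifying"):
            state_spectra(lfp, paths, fs=1000.0, w_bin=10.0)


class TestFdr:
    def brute_force_bh(self, p, q):
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p)
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= q * i / n:
                k = i
        mask = np.zeros(n, bool)
        mask[order[:k]] = True
        return mask

    def test_examples(self):
        assert fdr_correct([0.01, 0.02, 0.03, 0.04], 0.05).all()
        assert not fdr_correct([1.0, 1.0, 1.0], 0.05).any()
        assert fdr_correct([0.04], 0.05)[0]

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            p = rng.random(n) ** rng.uniform(0.5, 3.0)
            got = fdr_correct(p, 0.05)
            np.testing.assert_array_equal(got, self.brute_force_bh(p, 0.05))


class TestRf:
    def zmap(self, cy, cx, shape=(9, 12), amp=6.0):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        return amp * np.exp(-0.5 * (((yy - cy) / 1.0) ** 2
                                    + ((xx - cx) / 1.0) ** 2))

    def test_stouffer_variants(self):
        z = np.ones((4, 2, 2))
        np.testing.assert_allclose(stouffer_combine(z), 2.0)
        np.testing.assert_allclose(stouffer_combine(z, printed_variant=True),
                                   1.0)

    def test_identical_maps_full_overlap(self):
        maps = {"V1": [self.zmap(4, 6)] * 3, "V4": [self.zmap(4, 6)] * 3}
        out = rf_summary(maps)
        assert out.overlap == pytest.approx(1.0)
        assert out.separation == pytest.approx(0.0)

    def test_disjoint_maps_zero_overlap(self):
        maps = {"V1": [self.zmap(2, 2)] * 3, "V4": [self.zmap(7, 10)] * 3}
        out = rf_summary(maps)
        assert out.overlap == 0.0
        assert out.separation > 5.0

    def test_single_cell_center(self):
        z = np.zeros((1, 9, 12))
        z[0, 3, 5] = 10.0
        out = rf_summary({"V1": z, "V4": z})
        np.testing.assert_allclose(out.center["V1"], [3.0, 5.0])
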