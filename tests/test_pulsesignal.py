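"""Band-pass, spectra, HR readout, SNR, metrics, and the GREEN baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulseforge.clipio import FrameClip
from pulseforge.pulsesignal import (bandpass, estimate_hr, green_baseline,
                                    hr_metrics, power_spectrum, snr_db)

FPS = 30.0


def _sine(freq, d=512, fps=FPS, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(d) / fps + phase)


class TestBandpass:
    def test_inband_tone_amplitude_preserved(self):
        wave = _sine(1.5, d=1024)
        out = bandpass(wave, FPS)
        # compare RMS over the central region (edge transients excluded)
        ratio = np.std(out[100:-100]) / np.std(wave[100:-100])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_pure_dc_maps_to_zero(self):
        out = bandpass(np.full(600, 5.0), FPS)
        assert np.abs(out).max() < 1e-9

    def test_dc_offset_removed_from_tone(self):
        out = bandpass(np.full(600, 5.0) + _sine(1.2, d=600), FPS)
        assert abs(np.mean(out)) < 1e-3    # residual is edge transient only

    def test_drift_suppressed_tone_dominates(self):
        wave = 5.0 * _sine(0.05, d=1024) + _sine(1.2, d=1024)
        out = bandpass(wave, FPS)
        spec = power_spectrum(out, FPS)
        assert spec.peak_frequency() == pytest.approx(1.2, abs=0.05)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_sine(1.0), FPS, band=(0.6, 20.0))

    def test_output_length_preserved(self):
        assert bandpass(_sine(1.0, d=77), FPS).size == 77


class TestPowerSpectrum:
    def test_sinusoid_peak_on_exact_bin(self):
        # fps 30, n_fft 160 -> resolution 0.1875 Hz; 1.5 Hz is bin 8 exactly
        spec = power_spectrum(_sine(1.5, d=160), FPS, n_fft=160)
        k = int(np.argmax(spec.power))
        assert k == 8
        assert spec.freqs[k] == pytest.approx(1.5)

    def test_white_noise_flat_on_average(self):
        rng = np.random.default_rng(0)
        acc = None
        n_rep, d = 800, 128
        for _ in range(n_rep):
            spec = power_spectrum(rng.standard_normal(d), FPS, n_fft=d)
            acc = spec.power if acc is None else acc + spec.power
        mean_power = (acc / n_rep)[1:-1]     # interior bins share one scaling
        dev = mean_power.max() / mean_power.min()
        assert dev < 1.5                     # flat within Monte-Carlo tolerance

    def test_zero_wave_zero_power(self):
        spec = power_spectrum(np.zeros(64), FPS)
        np.testing.assert_array_equal(spec.power, 0.0)

    def test_grid_resolution(self):
        spec = power_spectrum(np.ones(64), FPS, n_fft=256)
        assert np.diff(spec.freqs)[0] == pytest.approx(FPS / 256)


class TestEstimateHR:
    def test_exact_bin_sinusoid(self):
        assert estimate_hr(_sine(1.5, d=160), FPS, n_fft=160) == pytest.approx(90.0)

    def test_off_grid_matches_periodogram_oracle(self):
        wave = _sine(1.0, d=160)
        got = estimate_hr(wave, FPS, n_fft=160)
        # independent brute-force periodogram argmax on the same grid
        freqs = np.arange(81) * FPS / 160
        mags = np.abs(np.fft.rfft(wave - wave.mean(), 160)) ** 2
        sel = (freqs >= 0.6) & (freqs <= 3.3)
        expect = 60.0 * freqs[sel][np.argmax(mags[sel])]
        assert got == pytest.approx(expect)

    def test_banding_excludes_strong_drift(self):
        wave = 10.0 * _sine(0.2, d=512) + 0.5 * _sine(1.2, d=512)
        assert estimate_hr(wave, FPS) == pytest.approx(72.0, abs=60 * FPS / 512)

    def test_degenerate_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_hr(np.zeros(128), FPS)

    def test_readout_grid_resolution_property(self):
        """Recovered HR is within one zero-padded readout bin of truth across
        the physiological range."""
        for hr in (45, 60, 75, 99, 123, 150, 180):
            wave = _sine(hr / 60.0, d=256)
            got = estimate_hr(wave, FPS, band=(0.6, 3.3), n_fft=1024)
            assert abs(got - hr) <= 60.0 * FPS / 1024 + 1e-9


class TestSNR:
    def test_pure_tone_high_snr(self):
        assert snr_db(_sine(1.2, d=512), 72.0, FPS) >= 20.0

    def test_noise_only_negative_on_average(self):
        rng = np.random.default_rng(1)
        vals = [snr_db(bandpass(rng.standard_normal(512), FPS), 90.0, FPS)
                for _ in range(40)]
        assert np.mean(vals) < 0.0

    def test_monotone_in_tone_amplitude(self):
        rng = np.random.default_rng(2)
        noise = rng.standard_normal(512)
        vals = [snr_db(_sine(1.5, d=512, amp=a) + noise, 90.0, FPS)
                for a in (0.25, 0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_scale_invariance(self):
        wave = _sine(1.1, d=512) + 0.3 * np.random.default_rng(3).standard_normal(512)
        a = snr_db(wave, 66.0, FPS)
        b = snr_db(1000.0 * wave, 66.0, FPS)
        assert a == pytest.approx(b, abs=1e-9)

    def test_reference_outside_band_rejected(self):
        with pytest.raises(ValueError):
            snr_db(_sine(1.0), 220.0, FPS)


class TestHRMetrics:
    def test_perfect_agreement(self):
        rep = hr_metrics([60, 72, 90], [60, 72, 90])
        assert rep.mae == rep.rmse == rep.mape == 0.0
        assert rep.rho == pytest.approx(1.0)
        assert rep.bland_altman.bias == 0.0

    def test_two_point_arithmetic(self):
        rep = hr_metrics([72, 60], [60, 72])
        assert rep.mae == pytest.approx(12.0)
        assert rep.rmse == pytest.approx(12.0)
        assert rep.mape == pytest.approx((20.0 + 100.0 * 12 / 72) / 2)
        assert rep.rho == pytest.approx(-1.0)

    def test_matches_streaming_oracle(self):
        """All metrics agree with an independent one-pass accumulation."""
        rng = np.random.default_rng(4)
        pred = rng.uniform(40, 180, 10_000)
        ref = rng.uniform(40, 180, 10_000)
        rep = hr_metrics(pred, ref)
        n = s_abs = s_sq = s_pct = s_d = s_d2 = 0.0
        sp = sr = spp = srr = spr = 0.0
        for p, r in zip(pred, ref):
            d = p - r
            n += 1
            s_abs += abs(d); s_sq += d * d; s_pct += abs(d) / r
            s_d += d; s_d2 += d * d
            sp += p; sr += r; spp += p * p; srr += r * r; spr += p * r
        assert rep.mae == pytest.approx(s_abs / n, abs=1e-10)
        assert rep.rmse == pytest.approx(np.sqrt(s_sq / n), abs=1e-10)
        assert rep.mape == pytest.approx(100 * s_pct / n, abs=1e-9)
        cov = spr / n - (sp / n) * (sr / n)
        rho = cov / np.sqrt((spp / n - (sp / n) ** 2) * (srr / n - (sr / n) ** 2))
        assert rep.rho == pytest.approx(rho, abs=1e-9)
        bias = s_d / n
        sd = np.sqrt(s_d2 / n - bias ** 2)
        assert rep.bland_altman.bias == pytest.approx(bias, abs=1e-9)
        assert rep.bland_altman.loa_high == pytest.approx(bias + 1.96 * sd, abs=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hr_metrics([60.0], [60.0, 70.0])

    def test_constant_reference_rho_undefined(self):
        rep = hr_metrics([61, 59], [60, 60])
        assert np.isnan(rep.rho)

    @given(st.lists(st.tuples(st.floats(30, 200), st.floats(30, 200)),
                    min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_rmse_dominates_mae(self, pairs):
        pred, ref = zip(*pairs)
        rep = hr_metrics(list(pred), list(ref))
        assert rep.rmse >= rep.mae - 1e-9
        assert rep.bland_altman.loa_low <= rep.bland_altman.bias \
            <= rep.bland_altman.loa_high


class TestGreenBaseline:
    def _pulsed_clip(self, freq=1.2, amp=0.02, d=300):
        base = np.full((d, 3, 8, 8), 0.5, np.float32)
        mod = _sine(freq, d=d, amp=amp)
        base[:, 1] += mod[:, None, None]
        return FrameClip(frames=np.clip(base, 0, 1), fps=FPS)

    def test_recovers_modulation_frequency(self):
        wave = green_baseline(self._pulsed_clip())
        assert estimate_hr(wave, FPS) == pytest.approx(72.0, abs=60 * FPS / 512)

    def test_static_clip_near_zero_output(self):
        clip = FrameClip(frames=np.full((200, 3, 8, 8), 0.4, np.float32), fps=FPS)
        assert np.abs(green_baseline(clip)).max() < 1e-8

    def test_linearity_in_modulation_amplitude(self):
        w1 = green_baseline(self._pulsed_clip(amp=0.01))
        w2 = green_baseline(self._pulsed_clip(amp=0.02))
        ratio = np.std(w2) / np.std(w1)
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_single_channel_clip_rejected(self):
        clip = FrameClip(frames=np.zeros((10, 1, 4, 4), np.float32), fps=FPS)
        with pytest.raises(ValueError):
            green_baseline(clip)
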