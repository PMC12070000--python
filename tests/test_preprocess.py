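"""Filtering, Hampel cleaning and normalization behaviour."""

import numpy as np
import pytest

from emgtorque import (
    ConfigError,
    DataError,
    EmgRecording,
    FilterSpec,
    HampelConfig,
    bandpass_filter,
    hampel_clean,
    normalize_minmax,
    notch_filter,
    preprocess_pipeline,
)

from oracles import hampel_flags_bruteforce, tone_power

FS = 2000.0


def _sine_rec(freq, fs=FS, duration=6.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return EmgRecording(amp * np.sin(2 * np.pi * freq * t), fs, ["ch"])


def _steady_gain_db(freq, spec, fs=FS):
    """Causal single-pass gain on a long sine, transient discarded."""
    rec = _sine_rec(freq, fs=fs)
    out = bandpass_filter(rec, spec, zero_phase=False).samples[0]
    tail = slice(int(4.0 * fs), None)
    g = np.sqrt(np.mean(out[tail] ** 2)) / np.sqrt(np.mean(rec.samples[0][tail] ** 2))
    return 20 * np.log10(g)


class TestBandpass:
    def test_half_power_at_band_edges(self):
        spec = FilterSpec(order=4, band_low_hz=10, band_high_hz=500)
        assert _steady_gain_db(10, spec) == pytest.approx(-3.01, abs=0.2)
        assert _steady_gain_db(500, spec) == pytest.approx(-3.01, abs=0.2)
        assert _steady_gain_db(100, spec) == pytest.approx(0.0, abs=0.5)

    def test_dc_settles_to_zero(self):
        rec = EmgRecording(np.full(4000, 2.5), FS, ["ch"])
        out = bandpass_filter(rec, FilterSpec(), zero_phase=False).samples[0]
        assert np.abs(out[-500:]).max() < 1e-3

    def test_drift_removed_passband_preserved(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 0.3 * t) + np.sin(2 * np.pi * 100 * t)
        rec = EmgRecording(x, FS, ["ch"])
        out = bandpass_filter(rec, FilterSpec()).samples[0]
        for f, bound, keeps in ((0.3, -40.0, False), (100.0, -1.0, True)):
            ratio_db = 5 * np.log10(
                tone_power(out, FS, f) / tone_power(rec.samples[0], FS, f)
            ) * 2
            if keeps:
                assert abs(ratio_db) < 1.0
            else:
                assert ratio_db < bound

    def test_band_edge_at_nyquist_rejected(self):
        rec = _sine_rec(100, duration=1.0)
        with pytest.raises(ConfigError, match="band_high_hz=1000"):
            bandpass_filter(rec, FilterSpec(band_high_hz=1000.0))

    def test_empty_signal_rejected(self):
        rec = EmgRecording(np.empty((1, 0)), FS, ["ch"])
        with pytest.raises(DataError):
            bandpass_filter(rec, FilterSpec())

    def test_filtering_is_linear(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 4000))
        spec = FilterSpec()
        f = lambda s: bandpass_filter(EmgRecording(s, FS, ["ch"]), spec).samples[0]
        np.testing.assert_allclose(f(2.0 * x - 3.0 * y), 2.0 * f(x) - 3.0 * f(y),
                                   rtol=1e-9, atol=1e-9)


class TestNotch:
    def test_mains_tone_suppressed(self):
        rec = _sine_rec(50)
        out = notch_filter(rec, FilterSpec()).samples[0]
        tail = slice(int(2 * FS), None)
        atten_db = 20 * np.log10(
            np.sqrt(np.mean(out[tail] ** 2)) / np.sqrt(np.mean(rec.samples[0][tail] ** 2))
        )
        assert atten_db < -30

    def test_off_notch_tone_preserved(self):
        rec = _sine_rec(75)
        out = notch_filter(rec, FilterSpec()).samples[0]
        tail = slice(int(2 * FS), None)
        gain_db = 20 * np.log10(
            np.sqrt(np.mean(out[tail] ** 2)) / np.sqrt(np.mean(rec.samples[0][tail] ** 2))
        )
        assert abs(gain_db) < 1.0

    def test_mixture_spectrum(self):
        t = np.arange(int(8 * FS)) / FS
        x = (np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 150 * t)
             + np.sin(2 * np.pi * 120 * t))
        rec = EmgRecording(x, FS, ["ch"])
        out = notch_filter(rec, FilterSpec()).samples[0]
        for f, min_atten in ((50.0, 25.0), (150.0, 25.0)):
            drop_db = 10 * np.log10(tone_power(rec.samples[0], FS, f) / tone_power(out, FS, f))
            assert drop_db > min_atten
        keep_db = 10 * np.log10(tone_power(rec.samples[0], FS, 120.0) / tone_power(out, FS, 120.0))
        assert abs(keep_db) < 1.5

    def test_harmonic_above_nyquist_skipped(self, caplog):
        rec = EmgRecording(np.random.default_rng(0).standard_normal(1000), 300.0, ["ch"])
        with caplog.at_level("WARNING", logger="emgtorque.preprocess"):
            out = notch_filter(rec, FilterSpec(band_high_hz=140, notch_harmonics=3))
        assert np.all(np.isfinite(out.samples))
        assert any("skipping notch harmonic" in m for m in caplog.messages)


class TestHampel:
    def test_constant_series_unflagged(self):
        x = np.full(100, 3.3)
        cleaned, mask = hampel_clean(x, HampelConfig(window_len=50))
        assert not mask.any()
        np.testing.assert_array_equal(cleaned, x)

    def test_injected_spike_flagged_and_replaced(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(750)
        x[400] = 10.0
        cfg = HampelConfig(window_len=750, k=3.0)
        cleaned, mask = hampel_clean(x, cfg)
        oracle = hampel_flags_bruteforce(x, 750, 3.0)
        np.testing.assert_array_equal(mask, oracle)
        assert mask[400]
        assert cleaned[400] == pytest.approx(np.median(x))

    @pytest.mark.parametrize("seed", range(20))
    def test_flags_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 2000))
        x = rng.standard_normal(n)
        for i in rng.integers(0, n, size=3):
            x[i] += rng.choice([-1, 1]) * rng.uniform(6, 15)
        wl = int(rng.integers(10, 400))
        _, mask = hampel_clean(x, HampelConfig(window_len=max(wl, 3), k=3.0))
        oracle = hampel_flags_bruteforce(x, max(wl, 3), 3.0)
        np.testing.assert_array_equal(mask, oracle)

    def test_window_longer_than_series(self):
        x = np.random.default_rng(1).standard_normal(100)
        _, mask = hampel_clean(x, HampelConfig(window_len=750))
        oracle = hampel_flags_bruteforce(x, 750, 3.0)
        np.testing.assert_array_equal(mask, oracle)

    def test_default_config_matches_protocol(self):
        cfg = HampelConfig()
        assert cfg.window_len == 750
        assert cfg.k == 3.0


class TestNormalize:
    def test_endpoints_map_to_unit_interval(self):
        norm, scale = normalize_minmax(np.array([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(norm, [-1.0, 0.0, 1.0])
        assert (scale.lo, scale.hi) == (0.0, 10.0)

    def test_output_range_exact(self):
        x = np.random.default_rng(2).standard_normal(500)
        norm, _ = normalize_minmax(x)
        assert norm.min() == -1.0 and norm.max() == 1.0

    def test_scale_roundtrip_bit_exact(self):
        x = np.random.default_rng(3).standard_normal(500)
        norm, scale = normalize_minmax(x)
        np.testing.assert_array_equal(scale.apply(x), norm)

    def test_idempotent(self):
        x = np.random.default_rng(5).standard_normal(500)
        norm, _ = normalize_minmax(x)
        again, _ = normalize_minmax(norm)
        np.testing.assert_allclose(again, norm, atol=1e-15)

    def test_constant_channel_rejected_by_name(self):
        with pytest.raises(DataError, match="vastus"):
            normalize_minmax(np.full(10, 1.0), name="vastus")


class TestPipeline:
    def test_artifact_removal_end_to_end(self):
        """DC offset, slow drift, mains hum and a spike all cleaned in one pass."""
        rng = np.random.default_rng(8)
        t = np.arange(int(8 * FS)) / FS
        emg = rng.standard_normal(t.size) * 0.2
        x = emg + 1.45 + 0.3 * np.sin(2 * np.pi * 0.35 * t) + 0.4 * np.sin(2 * np.pi * 50 * t)
        spike_at = 9000
        x[spike_at] += 5.0
        rec = EmgRecording(x, FS, ["ch"], angle=np.full(t.size, 90.0))

        # the band-pass alone takes the 1.45 V baseline (and drift) to zero
        bp = bandpass_filter(rec, FilterSpec()).samples[0]
        assert abs(bp.mean()) < 0.02

        result = preprocess_pipeline(rec)
        out = result.recording.samples[0]
        assert out.min() >= -1.0 and out.max() <= 1.0
        assert result.outlier_mask[0, spike_at]
        # baseline wander is gone: one-second block means stay put
        block_means = out[: 16 * 1000].reshape(16, 1000).mean(axis=1)
        assert np.ptp(block_means) < 0.05
        # the 50 Hz line vanishes into the local noise floor
        amp = np.abs(np.fft.rfft(out)) / out.size
        freqs = np.fft.rfftfreq(out.size, 1 / FS)
        peak = amp[(freqs > 49.5) & (freqs < 50.5)].max()
        floor = np.median(amp[(freqs > 40) & (freqs < 60)])
        assert peak < 3 * floor
        raw_amp = np.abs(np.fft.rfft(x)) / x.size
        raw_peak = raw_amp[(freqs > 49.5) & (freqs < 50.5)].max()
        raw_floor = np.median(raw_amp[(freqs > 40) & (freqs < 60)])
        assert raw_peak > 100 * raw_floor  # the artifact really was there

    def test_shape_preserved(self):
        rng = np.random.default_rng(9)
        rec = EmgRecording(rng.standard_normal((3, 4000)), FS, ["a", "b", "c"],
                           angle=np.full(4000, 60.0))
        result = preprocess_pipeline(rec)
        assert result.recording.samples.shape == (3, 4000)
        assert result.recording.angle is rec.angle

    def test_dead_channel_reported(self):
        rec = EmgRecording(np.zeros((1, 4000)), FS, ["dead_ch"],
                           angle=np.full(4000, 60.0))
        with pytest.raises(DataError, match="dead_ch"):
            preprocess_pipeline(rec)
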