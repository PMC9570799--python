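import numpy as np
import pandas as pd
import pytest

from pulsewave import (
    MultimodalRecording,
    PreprocessConfig,
    bandpass_ecg,
    invert_ppg,
    lowpass_zero_lag,
    preprocess_recording,
    remove_baseline,
    resample,
)
from pulsewave.preprocess import _pulses_point_down


def _rec(fs=200.0, **channels):
    return MultimodalRecording(pd.DataFrame(channels), fs)


class TestResample:
    def test_dc_preserved_and_length_scaled(self):
        rec = _rec(x=np.full(1000, 3.7))
        out = resample(rec, 1000.0)
        assert out.n_samples == 5000
        assert out.fs == 1000.0
        np.testing.assert_allclose(out["x"], 3.7, rtol=0, atol=1e-12)

    def test_sinusoid_bandlimited_oracle(self):
        """A 5 Hz tone resampled 200->1000 Hz matches the analytic sinusoid."""
        t = np.arange(2000) / 200.0
        rec = _rec(x=np.sin(2 * np.pi * 5 * t))
        out = resample(rec, 1000.0)
        t5 = np.arange(out.n_samples) / 1000.0
        ref = np.sin(2 * np.pi * 5 * t5)
        edge = 100  # 100 ms
        err = np.abs(out["x"][edge:-edge] - ref[edge:-edge])
        assert err.max() < 1e-3

    def test_downsampling_rejected_and_empty_errors(self):
        rec = _rec(x=np.ones(100))
        with pytest.raises(ValueError):
            resample(rec, 100.0)
        with pytest.raises(ValueError):
            resample(_rec(x=np.array([])), 1000.0)


class TestLowpassZeroLag:
    def test_dc_identity(self):
        x = np.full(2000, 1.5)
        np.testing.assert_allclose(lowpass_zero_lag(x, 1000.0), x, atol=1e-9)

    @pytest.mark.parametrize("freq", [2.0, 5.0, 10.0])
    def test_in_band_peak_unshifted(self, freq):
        """Zero-lag contract: in-band tone peaks move by at most one sample."""
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_zero_lag(x, fs)
        period = slice(int(fs), int((1 + 1 / freq) * fs))  # one mid-record cycle
        i = int(np.argmax(x[period]))
        quarter = int(fs / (4 * freq))
        j = i - quarter + int(np.argmax(y[period][i - quarter: i + quarter]))
        assert abs(j - i) <= 1

    def test_stopband_attenuation_matches_butterworth(self):
        """Residual 40 Hz amplitude equals the squared 4th-order Butterworth
        magnitude at 40 Hz with fc = 20 Hz: 1/(1 + (40/20)^8) = 1/257."""
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        y = lowpass_zero_lag(np.sin(2 * np.pi * 40 * t), fs)
        mid = y[int(2 * fs): int(8 * fs)]
        measured = (mid.max() - mid.min()) / 2
        assert measured == pytest.approx(1.0 / 257.0, rel=0.05)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            lowpass_zero_lag(np.ones(10), 1000.0)


class TestRemoveBaseline:
    def test_polynomial_reproduction(self):
        x = np.linspace(0, 5, 3000)
        detrended, baseline = remove_baseline(x, 1000.0)
        assert np.abs(detrended).max() < 1e-6 * np.ptp(x)

    def test_frame_is_1501_at_1khz(self):
        from scipy.signal import savgol_filter

        x = np.random.default_rng(0).normal(size=4000)
        _, baseline = remove_baseline(x, 1000.0, polyorder=3, frame_s=1.5)
        np.testing.assert_allclose(baseline, savgol_filter(x, 1501, 3))

    def test_exact_additive_decomposition(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        detrended, baseline = remove_baseline(x, 1000.0)
        np.testing.assert_allclose(detrended + baseline, x, rtol=0, atol=1e-12)

    def test_extracts_slow_oscillation(self):
        """Baseline tracks a 0.2 Hz drift under a 1.5 Hz pulse train."""
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        slow = 0.5 * np.sin(2 * np.pi * 0.2 * t)
        pulses = np.clip(np.sin(2 * np.pi * 1.5 * t), 0.6, None) - 0.6
        _, baseline = remove_baseline(slow + pulses, fs)
        mid = slice(int(2 * fs), int(18 * fs))
        r = np.corrcoef(baseline[mid], slow[mid])[0, 1]
        assert r > 0.99

    def test_shorter_than_frame_errors(self):
        with pytest.raises(ValueError):
            remove_baseline(np.ones(1000), 1000.0, frame_s=1.5)


class TestInvertAndEcgBand:
    def test_invert_is_negation_and_involution(self):
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(invert_ppg(x), [-1.0, 2.0, -3.0])
        np.testing.assert_array_equal(invert_ppg(invert_ppg(x)), x)

    def test_bandpass_rejects_dc(self):
        y = bandpass_ecg(np.full(5000, 2.0), 1000.0)
        assert np.abs(y).max() < 1e-6 * 2.0 + 1e-9

    def test_bandpass_passes_10hz(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        y = bandpass_ecg(np.sin(2 * np.pi * 10 * t), fs)
        mid = y[int(2 * fs): int(8 * fs)]
        assert (mid.max() - mid.min()) / 2 == pytest.approx(1.0, rel=0.02)

    def test_bandpass_nyquist_guard(self):
        with pytest.raises(ValueError):
            bandpass_ecg(np.ones(5000), 60.0, high=40.0)


class TestPreprocessRecording:
    def test_output_rate_polarity_and_order(self, clean_recording):
        rec, truth = clean_recording
        pp = preprocess_recording(rec)
        assert pp.fs == 1000.0
        assert pp.channels == rec.channels
        for ch in ("ppg_r", "ppg_ir", "fcg"):
            assert pp[ch].max() > abs(pp[ch].min())  # positive systolic peaks
        assert any(s.get("stage") == "preprocess" for s in pp.meta["processing"])

    def test_systolic_peaks_near_truth_after_full_chain(self, clean_preprocessed):
        """Per-beat maxima of the preprocessed ppg_r lie within 2 ms of the
        generator's systolic anchor times."""
        pp, truth = clean_preprocessed
        fs = pp.fs
        x = pp["ppg_r"]
        checked = 0
        for f in truth.complete("ppg_r"):
            if not 1.0 < f.sys_peak_t < pp.duration - 1.0:
                continue
            lo, hi = int((f.sys_peak_t - 0.2) * fs), int((f.sys_peak_t + 0.2) * fs)
            i = lo + int(np.argmax(x[lo:hi]))
            assert abs(i / fs - f.sys_peak_t) <= 0.002
            checked += 1
        assert checked >= 30

    def test_missing_channel_named(self, clean_recording):
        rec, _ = clean_recording
        crippled = MultimodalRecording(rec.data.drop(columns=["ppg_ir"]), rec.fs)
        with pytest.raises(ValueError, match="ppg_ir"):
            preprocess_recording(crippled)

    def test_near_idempotent(self, realistic_recording):
        """A second pass is not an error and changes little: no polarity
        flip, high correlation; the residual change is the baseline stage
        removing another slice of the pulse fundamental (the 1.5 s frame
        passes ~29% of a ~1 Hz tone), bounded well below the pulse itself."""
        rec, _ = realistic_recording
        once = preprocess_recording(rec)
        twice = preprocess_recording(once)
        for ch in ("ppg_r", "ppg_ir", "fcg"):
            a, b = once[ch], twice[ch]
            assert np.corrcoef(a, b)[0, 1] > 0.98
            assert np.sqrt(np.mean((a - b) ** 2)) < 0.2 * np.sqrt(np.mean(a**2))

    def test_polarity_detector(self, clean_preprocessed):
        pp, _ = clean_preprocessed
        assert not _pulses_point_down(pp["fcg"])
        assert _pulses_point_down(-pp["fcg"])
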