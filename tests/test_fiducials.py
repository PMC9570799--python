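import numpy as np
import pytest

from pulsewave import (
    FiducialSet,
    detect_pw_fiducials,
    detect_r_peaks,
    segment_beats,
)
from pulsewave.preprocess import bandpass_ecg, resample
from pulsewave import generate_recording
from tests.conftest import clean_config, complete_pairs


@pytest.fixture(scope="module")
def clean_ecg_1khz():
    rec, truth = generate_recording(clean_config(n_beats=10))
    rec = resample(rec, 1000.0)
    return bandpass_ecg(rec["ecg"], 1000.0), truth


class TestDetectRPeaks:
    def test_clean_ten_beats_at_60_bpm(self, clean_ecg_1khz):
        ecg, truth = clean_ecg_1khz
        r = detect_r_peaks(ecg, 1000.0)
        assert len(r) == 10
        np.testing.assert_allclose(np.diff(r), 1.0, atol=0.005)
        np.testing.assert_allclose(r, truth.r_peak_times, atol=0.005)

    def test_all_zero_returns_empty(self):
        assert len(detect_r_peaks(np.zeros(5000), 1000.0)) == 0

    def test_short_record_errors(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(np.zeros(1500), 1000.0)

    def test_noisy_sensitivity_and_ppv(self):
        """SNR 10 dB white noise: sensitivity and PPV both at least 0.99."""
        rec, truth = generate_recording(clean_config(n_beats=100, seed=3))
        rec = resample(rec, 1000.0)
        ecg = rec["ecg"]
        rng = np.random.default_rng(42)
        noise_sd = np.sqrt(np.mean(ecg**2)) / np.sqrt(10.0)
        noisy = bandpass_ecg(ecg + rng.normal(0, noise_sd, len(ecg)), 1000.0)
        r = detect_r_peaks(noisy, 1000.0)
        tp = sum(np.min(np.abs(r - t)) < 0.05 for t in truth.r_peak_times)
        sens = tp / len(truth.r_peak_times)
        ppv = sum(np.min(np.abs(truth.r_peak_times - x)) < 0.05 for x in r) / len(r)
        assert sens >= 0.99
        assert ppv >= 0.99


class TestDetectPwFiducials:
    def test_detector_exact_on_unfiltered_signal(self):
        """On a clean 1 kHz signal with no filtering in the way, every
        marker is recovered within one sample of generator truth."""
        cfg = clean_config(n_beats=24, fs_out=1000.0)
        rec, truth = generate_recording(cfg)
        pw = -rec["ppg_r"]  # undo raw polarity; no other processing
        fids = detect_pw_fiducials(pw, rec.fs, truth.r_peak_times)
        pairs = complete_pairs(fids, truth.fiducials["ppg_r"])
        assert len(pairs) >= 18
        for att in ("foot_t", "sys_peak_t", "notch_t", "dia_peak_t"):
            errs = [abs(getattr(d, att) - getattr(t, att)) for d, t in pairs]
            assert max(errs) <= 1.1e-3, (att, max(errs))

    def test_noise_free_recovery_through_full_pipeline(self, clean_preprocessed):
        """Through the full conditioning chain the markers stay within a few
        ms of truth (the baseline-removal stage inevitably takes ~29% of
        the ~1 Hz pulse fundamental with it, slightly displacing extrema)."""
        pp, truth = clean_preprocessed
        for ch in ("ppg_r", "fcg"):
            fids = detect_pw_fiducials(pp[ch], pp.fs, truth.r_peak_times)
            pairs = complete_pairs(fids, truth.fiducials[ch])
            assert len(pairs) >= 30
            # the diastolic peak is the gentlest extremum and moves the most
            bounds = {"foot_t": 5e-3, "sys_peak_t": 5e-3,
                      "notch_t": 6e-3, "dia_peak_t": 15e-3}
            for att, bound in bounds.items():
                errs = [abs(getattr(d, att) - getattr(t, att)) for d, t in pairs]
                assert max(errs) < bound, (ch, att, max(errs))

    def test_four_markers_and_ordering(self, clean_preprocessed):
        pp, truth = clean_preprocessed
        fids = detect_pw_fiducials(pp["ppg_r"], pp.fs, truth.r_peak_times)
        ok = [f for f in fids if f.quality_flag == "ok"]
        assert len(ok) >= 30
        for f in ok:
            assert f.foot_t < f.sys_peak_t < f.notch_t < f.dia_peak_t
            assert f.sys_peak_a > f.foot_a

    def test_missing_notch_on_monotone_decay(self):
        """A beat whose diastolic lobe is filled in (pure decay after the
        systolic peak) is flagged missing_notch."""
        fs = 1000.0
        t = np.arange(int(0.9 * fs)) / fs
        beat = np.where(
            t < 0.15, 0.5 * (1 - np.cos(np.pi * t / 0.15)), np.exp(-(t - 0.15) / 0.25)
        )
        pw = np.concatenate([beat] * 8)
        r_peaks = 0.9 * np.arange(8) - 0.05
        fids = detect_pw_fiducials(pw, fs, r_peaks[r_peaks >= 0], edge_guard=0.0)
        flags = {f.quality_flag for f in fids if f.quality_flag != "partial"}
        assert flags == {"missing_notch"}

    def test_translation_equivariance(self, clean_preprocessed):
        """Shifting the record by k samples shifts every fiducial by k/fs."""
        pp, truth = clean_preprocessed
        fs = pp.fs
        k = 137
        x = pp["ppg_r"]
        fids = detect_pw_fiducials(x, fs, truth.r_peak_times)
        shifted = detect_pw_fiducials(
            np.concatenate([x[:k][::-1], x[:-k]]), fs, truth.r_peak_times + k / fs
        )
        base = {f.beat_index: f for f in fids if f.quality_flag == "ok"}
        moved = {f.beat_index: f for f in shifted if f.quality_flag == "ok"}
        common = sorted((set(base) & set(moved)) - {0, max(base)})
        assert len(common) >= 20
        for bi in common:
            for att in ("foot_t", "sys_peak_t", "notch_t", "dia_peak_t"):
                assert getattr(moved[bi], att) - getattr(base[bi], att) == pytest.approx(
                    k / fs, abs=1e-9
                )

    def test_empty_r_peaks_errors(self):
        with pytest.raises(ValueError):
            detect_pw_fiducials(np.zeros(3000), 1000.0, np.array([]))

    def test_ecg_free_fallback_finds_beats(self, clean_preprocessed):
        pp, truth = clean_preprocessed
        fids = detect_pw_fiducials(pp["ppg_r"], pp.fs, None)
        ok = [f for f in fids if f.quality_flag == "ok"]
        true_sys = np.array([f.sys_peak_t for f in truth.complete("ppg_r")])
        hits = sum(np.min(np.abs(true_sys - f.sys_peak_t)) < 0.01 for f in ok)
        assert hits >= 0.8 * len(ok) and len(ok) >= 20


class TestSegmentBeats:
    def _fids(self, foot_samples, fs):
        return [
            FiducialSet(beat_index=i, foot_t=s / fs, foot_a=0.0,
                        sys_peak_t=s / fs + 0.1, sys_peak_a=1.0)
            for i, s in enumerate(foot_samples)
        ]

    def test_fencepost_and_boundaries(self):
        fs = 100.0
        pw = np.arange(1000, dtype=float)
        feet = [50 + 90 * i for i in range(10)]
        segs = segment_beats(pw, fs, self._fids(feet, fs))
        assert len(segs) == 9
        for (bi, seg), lo, hi in zip(segs, feet[:-1], feet[1:]):
            assert seg[0] == pw[lo]
            assert len(seg) == hi - lo

    def test_concatenation_reconstructs(self):
        fs = 100.0
        rng = np.random.default_rng(0)
        pw = rng.normal(size=500)
        feet = [30, 120, 260, 333, 480]
        segs = segment_beats(pw, fs, self._fids(feet, fs))
        np.testing.assert_array_equal(
            np.concatenate([s for _, s in segs]), pw[30:480]
        )

    def test_fewer_than_two_feet(self):
        assert segment_beats(np.zeros(100), 100.0, self._fids([10], 100.0)) == []
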