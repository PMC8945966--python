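import numpy as np
import pytest

from ecg2bp.errors import InsufficientDataError, SchemaError
from ecg2bp.labeling import (
    detect_qrs,
    find_abp_extrema,
    label_frame,
    label_frames,
    rhythm_summary,
)
from ecg2bp.preprocess import FramePair, lowpass_filter, preprocess_record, remove_baseline_wavelet
from ecg2bp.signal_io import BeatAnnotation
from ecg2bp.synth import SyntheticConfig, simulate_ecg, simulate_record

FS = 125.0


class TestFindAbpExtrema:
    def test_three_beat_segment(self, clean_record):
        rec, truth = clean_record
        lo, hi = truth.abp_trough_indices[0], truth.abp_trough_indices[3] + 5
        peaks, troughs = find_abp_extrema(rec.channels["abp"][lo:hi], rec.fs)
        assert len(peaks) == 3
        np.testing.assert_allclose(rec.channels["abp"][lo:hi][peaks.indices], 120.0)
        assert len(troughs) == 3  # interior troughs; the one at sample 0 is cut
        np.testing.assert_allclose(rec.channels["abp"][lo:hi][troughs.indices], 80.0)

    def test_flat_signal_degenerate(self):
        peaks, troughs = find_abp_extrema(np.full(500, 100.0), FS)
        assert len(peaks) == 0 and len(troughs) == 0

    def test_single_cycle(self, clean_record):
        rec, truth = clean_record
        lo = truth.abp_trough_indices[1] - 5
        hi = truth.abp_trough_indices[2] + 5
        peaks, troughs = find_abp_extrema(rec.channels["abp"][lo:hi], rec.fs)
        assert len(peaks) == 1

    def test_peaks_and_troughs_alternate(self, noisy_record):
        rec, _ = noisy_record
        peaks, troughs = find_abp_extrema(rec.channels["abp"], rec.fs)
        merged = sorted([(i, "p") for i in peaks.indices] + [(i, "t") for i in troughs.indices])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestLabelFrame:
    def test_mean_of_extrema(self):
        # piecewise-linear frame with peaks {120, 122} and troughs {78, 80}
        knots_i = [0, 16, 48, 80, 112, 127]
        knots_v = [100.0, 120.0, 78.0, 122.0, 80.0, 100.0]
        abp = np.interp(np.arange(128), knots_i, knots_v)
        frame = FramePair(ecg=np.zeros(128), abp=abp, frame_index=0)
        lab = label_frame(frame, FS)
        assert lab.n_peaks == 2 and lab.n_troughs == 2
        assert lab.sbp == pytest.approx(121.0)
        assert lab.dbp == pytest.approx(79.0)

    def test_noise_free_synth_exact(self, clean_record):
        rec, _ = clean_record
        frames = preprocess_record(rec)
        for f in frames:
            lab = label_frame(f, rec.fs)
            if lab.valid:
                assert lab.sbp == pytest.approx(120.0, abs=1e-9)
                assert lab.dbp == pytest.approx(80.0, abs=1e-9)

    def test_frame_without_cycle_flagged_invalid(self):
        frame = FramePair(ecg=np.zeros(128), abp=np.full(128, 100.0), frame_index=0)
        lab = label_frame(frame, FS)
        assert not lab.valid and lab.n_peaks == 0

    def test_missing_abp_rejected(self):
        frame = FramePair(ecg=np.zeros(128), abp=None, frame_index=0)
        with pytest.raises(SchemaError):
            label_frame(frame, FS)

    def test_implausible_pressures_flagged(self):
        t = np.arange(128) / FS
        wave = 100 + 300 * np.maximum(np.sin(2 * np.pi * 1.5 * t), 0)
        frame = FramePair(ecg=np.zeros(128), abp=wave, frame_index=0)
        assert not label_frame(frame, FS).valid  # SBP > 250 mmHg


class TestDetectQrs:
    def test_clean_recovery_within_one_sample(self):
        cfg = SyntheticConfig(duration_s=10, hr_bpm=60, hr_sd=0, noise_sd=0,
                              powerline_amp=0, wander_amp=0, seed=0)
        rec, truth = simulate_ecg(cfg)
        ann = detect_qrs(lowpass_filter(rec.channels["ecg"], FS), FS)
        assert len(ann) == truth.n_beats == 10
        assert np.max(np.abs(ann.indices - truth.r_peak_indices)) <= 1

    def test_moderate_noise_sensitivity(self):
        """noise sd at 10% of R amplitude: >= 9/10 beats, no false positives."""
        cfg = SyntheticConfig(duration_s=10, hr_bpm=60, hr_sd=0, noise_sd=0.1, seed=1)
        rec, truth = simulate_ecg(cfg)
        cond = remove_baseline_wavelet(lowpass_filter(rec.channels["ecg"], FS), FS)
        ann = detect_qrs(cond, FS)
        tol = 0.05 * FS
        gt = truth.r_peak_indices
        matched = sum(np.min(np.abs(gt - d)) <= tol for d in ann.indices)
        assert matched >= 9
        assert len(ann) - matched == 0

    def test_flat_signal_empty(self):
        with pytest.warns(UserWarning):
            ann = detect_qrs(np.zeros(1250), FS)
        assert len(ann) == 0


class TestRhythmSummary:
    def test_definition(self):
        ann = BeatAnnotation(np.array([0, 125, 250]), "r_peak")
        rs = rhythm_summary(ann, FS)
        np.testing.assert_allclose(rs.rr_s, [1.0, 1.0])
        np.testing.assert_allclose(rs.hr_bpm, [60.0, 60.0])

    def test_arithmetic(self):
        rs = rhythm_summary(BeatAnnotation(np.array([0, 100]), "r_peak"), FS)
        np.testing.assert_allclose(rs.rr_s, [0.8])
        np.testing.assert_allclose(rs.hr_bpm, [75.0])

    def test_insufficient_peaks_rejected(self):
        with pytest.raises(InsufficientDataError):
            rhythm_summary(BeatAnnotation(np.array([42]), "r_peak"), FS)

    def test_hr_ramp_recovered(self):
        """Rising-rate record: detected HR trend follows the simulator's beats."""
        cfg = SyntheticConfig(duration_s=30, hr_bpm=75, hr_sd=0, noise_sd=0.03, seed=8)
        rec, truth = simulate_ecg(cfg)
        cond = remove_baseline_wavelet(lowpass_filter(rec.channels["ecg"], FS), FS)
        rs = rhythm_summary(detect_qrs(cond, FS), FS)
        true_rr = np.diff(truth.beat_times_s)
        assert rs.mean_hr_bpm == pytest.approx(60.0 / true_rr.mean(), abs=1.0)


class TestLabelOracle:
    def test_labels_match_ground_truth_on_noise_free_abp(self):
        """Central correctness oracle: frame labels == simulator frame truth."""
        for seed in (0, 1, 2):
            cfg = SyntheticConfig(duration_s=30, hr_sd=3.0, bp_drift=4.0,
                                  coupling=(90.0, 0.5), coupling_noise_sd=0.0,
                                  pulse_pressure_sd=0.0, noise_sd=0.0,
                                  powerline_amp=0.0, wander_amp=0.0, seed=seed)
            rec, truth = simulate_record(cfg)
            frames = preprocess_record(rec)
            labels = label_frames(frames, rec.fs)
            refs = truth.frame_reference(rec.n_samples)
            for lab, ref in zip(labels, refs):
                if ref is not None and lab.valid:
                    assert lab.sbp == pytest.approx(ref[0], abs=1e-6)
                    assert lab.dbp == pytest.approx(ref[1], abs=1e-6)
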