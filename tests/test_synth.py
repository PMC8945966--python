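import numpy as np
import pytest

from ecg2bp.errors import ConfigError
from ecg2bp.synth import (
    SyntheticConfig,
    simulate_abp,
    simulate_dataset,
    simulate_ecg,
    simulate_record,
)


def brute_force_cycle_extrema(abp, trough_indices):
    """Independent per-cycle max/min scan between consecutive ABP onsets."""
    maxima, minima = [], []
    for lo, hi in zip(trough_indices[:-1], trough_indices[1:]):
        seg = abp[lo:hi]
        maxima.append(seg.max())
        minima.append(seg.min())
    return np.array(maxima), np.array(minima)


class TestSimulateEcg:
    def test_deterministic_beat_placement(self):
        cfg = SyntheticConfig(duration_s=10, hr_bpm=60, hr_sd=0, seed=0)
        _, truth = simulate_ecg(cfg)
        assert truth.n_beats == 10
        np.testing.assert_allclose(np.diff(truth.beat_times_s), 1.0)

    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(duration_s=10, seed=42)
        r1, _ = simulate_ecg(cfg)
        r2, _ = simulate_ecg(cfg)
        np.testing.assert_array_equal(r1.channels["ecg"], r2.channels["ecg"])

    def test_clean_signal_mean_near_isoelectric(self):
        # frozen oracle: integrating the Gaussian template analytically,
        # sum(amp_i * width_i * sqrt(2*pi)) per 1-s beat = net area 0.0576 mV*s
        # (P 0.12*0.04 + Q -0.15*0.012 + R 1.0*0.012 + S -0.25*0.012 + T 0.3*0.05
        #  = 0.022986 mV*s scaled by sqrt(2*pi)), i.e. a mean offset of ~0.058 mV
        cfg = SyntheticConfig(duration_s=10, hr_bpm=60, hr_sd=0, noise_sd=0,
                              powerline_amp=0, wander_amp=0, seed=0)
        rec, _ = simulate_ecg(cfg)
        area_per_beat = np.sqrt(2 * np.pi) * (
            0.12 * 0.040 - 0.15 * 0.012 + 1.0 * 0.012 - 0.25 * 0.012 + 0.3 * 0.050)
        expected_mean = area_per_beat / 1.0  # one beat per second
        assert rec.channels["ecg"].mean() == pytest.approx(expected_mean, abs=0.01)

    def test_powerline_spectral_peak(self):
        cfg = SyntheticConfig(duration_s=20, powerline_amp=0.5, powerline_hz=50.0,
                              noise_sd=0.0, wander_amp=0.0, seed=1)
        rec, _ = simulate_ecg(cfg)
        x = rec.channels["ecg"]
        f = np.fft.rfftfreq(x.size, 1 / cfg.fs)
        amp = np.abs(np.fft.rfft(x))
        band = amp[(f > 40) & (f <= 62.5)]
        fband = f[(f > 40) & (f <= 62.5)]
        assert abs(fband[np.argmax(band)] - 50.0) < 0.2

    def test_too_short_duration_rejected(self):
        with pytest.raises(ConfigError):
            simulate_ecg(SyntheticConfig(duration_s=0.4, hr_bpm=60))

    def test_aliasing_warning(self):
        with pytest.warns(UserWarning, match="alias"):
            SyntheticConfig(fs=100.0, powerline_hz=60.0, powerline_amp=0.1)


class TestSimulateAbp:
    def test_constant_bp_exact_extrema(self, clean_config, clean_record):
        rec, truth = clean_record
        abp = rec.channels["abp"]
        assert np.all(truth.per_beat_sbp == clean_config.sbp_mmHg)
        assert np.all(truth.per_beat_dbp == clean_config.dbp_mmHg)
        mx, mn = brute_force_cycle_extrema(abp, truth.abp_trough_indices)
        np.testing.assert_array_equal(mx, truth.per_beat_sbp[:-1])
        np.testing.assert_array_equal(mn, truth.per_beat_dbp[:-1])

    def test_varying_bp_extrema_match_brute_force(self):
        """Per-cycle maxima and fiducial sample values equal the stored truth."""
        cfg = SyntheticConfig(duration_s=30, hr_sd=3.0, bp_drift=5.0,
                              noise_sd=0.0, powerline_amp=0, wander_amp=0, seed=9)
        rec, truth = simulate_record(cfg)
        abp = rec.channels["abp"]
        mx, _ = brute_force_cycle_extrema(abp, truth.abp_trough_indices)
        np.testing.assert_allclose(mx, truth.per_beat_sbp[:-1], atol=1e-12)
        # the rendered signal attains SBP/DBP exactly at the fiducial samples
        np.testing.assert_array_equal(abp[truth.abp_peak_indices], truth.per_beat_sbp)
        np.testing.assert_array_equal(abp[truth.abp_trough_indices], truth.per_beat_dbp)

    def test_sbp_exceeds_dbp_everywhere(self):
        for seed in range(3):
            _, truth = simulate_record(SyntheticConfig(duration_s=20, seed=seed))
            assert np.all(truth.per_beat_sbp > truth.per_beat_dbp)

    def test_hr_coupling_is_monotone(self):
        """With positive coupling, faster beats carry higher SBP."""
        cfg = SyntheticConfig(duration_s=60, hr_sd=8.0, bp_drift=0.0,
                              coupling=(90.0, 0.5), coupling_noise_sd=0.0,
                              pulse_pressure_sd=0.0, seed=2)
        _, truth = simulate_record(cfg)
        hrs = truth._hrs
        np.testing.assert_allclose(truth.per_beat_sbp, 90.0 + 0.5 * np.asarray(hrs))


class TestSimulateDataset:
    def test_regeneration_reproduces_all_records(self):
        cfg = SyntheticConfig(duration_s=10, seed=5)
        a = simulate_dataset(cfg, 3)
        b = simulate_dataset(cfg, 3)
        assert len(a) == 3
        for (ra, _), (rb, _) in zip(a, b):
            np.testing.assert_array_equal(ra.channels["ecg"], rb.channels["ecg"])
            np.testing.assert_array_equal(ra.channels["abp"], rb.channels["abp"])

    def test_records_are_distinct(self):
        cfg = SyntheticConfig(duration_s=10, seed=5)
        recs = simulate_dataset(cfg, 3)
        assert not np.array_equal(recs[0][0].channels["ecg"], recs[1][0].channels["ecg"])

    def test_zero_jitter_keeps_baselines(self):
        cfg = SyntheticConfig(duration_s=10, seed=5)
        recs = simulate_dataset(cfg, 3, hr_jitter_sd=0.0, pp_jitter_sd=0.0)
        for _, truth in recs:
            rr = np.diff(truth.beat_times_s)
            assert abs(60.0 / rr.mean() - cfg.hr_bpm) < 4 * cfg.hr_sd

    def test_pooled_sbp_follows_coupling(self):
        """Law of large numbers: pooled mean SBP ~ a + b * (pooled mean HR)."""
        cfg = SyntheticConfig(duration_s=20, seed=17)
        recs = simulate_dataset(cfg, 50)
        sbp = np.concatenate([t.per_beat_sbp for _, t in recs])
        hrs = np.concatenate([t._hrs for _, t in recs])
        a, b = cfg.coupling
        assert sbp.mean() == pytest.approx(a + b * hrs.mean(), abs=0.5)

    def test_n_records_validated(self):
        with pytest.raises(ConfigError):
            simulate_dataset(SyntheticConfig(), 0)
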