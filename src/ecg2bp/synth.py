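"""Coupled synthetic ECG/ABP generator with known ground truth.

The generator emulates ICU-monitor style paired recordings: a beat-synchronous
ECG built from five Gaussian waves (P, Q, R, S, T) per beat, and an arterial
pressure channel whose per-cycle maximum/minimum are the beat's systolic and
diastolic pressures.  Both channels share the same beat times, so beat timing
recovered from the ECG carries blood-pressure information.

The statistical link that makes BP learnable from ECG alone is an explicit
heart-rate coupling

    SBP_k = a + b * HR_k + eps_k,      eps_k ~ N(0, coupling_noise_sd**2)

with ``HR_k`` the instantaneous heart rate of beat ``k`` (defaults
``a = 90 mmHg``, ``b = 0.5 mmHg/bpm``, noise sd ``2 mmHg``).  Diastolic
pressure is systolic minus a configurable pulse pressure plus independent
noise.  A slow sinusoidal BP drift models within-record variation that the
ECG cannot explain.

ECG nuisances — additive broadband noise, a power-line sinusoid, and
low-frequency baseline wander — are controlled per config field.

The ABP channel is rendered so that each cycle's extrema land *exactly* on
sample values: the systolic peak sample equals that beat's SBP and the
diastolic onset sample equals its DBP.  This makes the generator an exact
oracle for downstream label extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .signal_io import WaveformRecord

# Gaussian ECG template: (time offset from R in s, amplitude in mV, width in s)
_ECG_WAVES = (
    (-0.20, 0.12, 0.040),   # P
    (-0.035, -0.15, 0.012),  # Q
    (0.0, 1.00, 0.012),      # R
    (0.035, -0.25, 0.012),   # S
    (0.25, 0.30, 0.050),     # T
)

# Fraction of the cycle from ABP onset to systolic peak.
_SYSTOLIC_PEAK_FRAC = 0.3
# Delay from R peak to ABP upstroke onset (s) — a pulse-arrival-time stand-in.
_ABP_ONSET_DELAY_S = 0.1
# Steepness of the exponential diastolic decay (dimensionless).
_DECAY_TAU = 3.0


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic paired ECG/ABP record.

    Identical seed + config produce bit-identical output.
    """

    duration_s: float = 60.0
    fs: float = 125.0
    hr_bpm: float = 75.0
    hr_sd: float = 2.0            # beat-to-beat HR variability, bpm
    sbp_mmHg: float = 120.0       # baseline SBP when coupling is disabled
    dbp_mmHg: float = 80.0        # implies default pulse pressure 40 mmHg
    bp_drift: float = 2.0         # amplitude of slow sinusoidal SBP drift, mmHg
    coupling: tuple[float, float] | None = (90.0, 0.5)  # SBP = a + b*HR + eps
    coupling_noise_sd: float = 2.0  # sd of eps, mmHg
    pulse_pressure_sd: float = 2.0  # sd of per-beat pulse-pressure noise, mmHg
    noise_sd: float = 0.05        # broadband ECG noise sd, mV
    powerline_hz: float = 60.0
    powerline_amp: float = 0.02   # mV
    wander_hz: float = 0.2
    wander_amp: float = 0.1       # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigError("duration_s and fs must be positive")
        if self.sbp_mmHg <= self.dbp_mmHg:
            raise ConfigError("sbp_mmHg must exceed dbp_mmHg")
        if self.hr_bpm <= 0:
            raise ConfigError("hr_bpm must be positive")
        if self.powerline_amp > 0 and self.fs < 2 * self.powerline_hz:
            warnings.warn(
                f"fs={self.fs} Hz cannot represent {self.powerline_hz} Hz interference; "
                "it will alias", stacklevel=2,
            )

    @property
    def pulse_pressure(self) -> float:
        return self.sbp_mmHg - self.dbp_mmHg


@dataclass
class GroundTruth:
    """Per-beat ground truth attached to a synthetic record.

    ``abp_peak_indices`` / ``abp_trough_indices`` are the sample positions at
    which the rendered ABP channel attains each beat's SBP / DBP exactly.
    """

    beat_times_s: np.ndarray
    fs: float
    per_beat_sbp: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_beat_dbp: np.ndarray = field(default_factory=lambda: np.empty(0))
    abp_peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    abp_trough_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def r_peak_indices(self) -> np.ndarray:
        return np.rint(self.beat_times_s * self.fs).astype(int)

    @property
    def n_beats(self) -> int:
        return self.beat_times_s.size

    def frame_reference(self, n_samples: int, frame_len: int = 128) -> "list[tuple[float, float] | None]":
        """Reference (SBP, DBP) per non-overlapping frame of ``frame_len``.

        A frame's reference SBP is the mean of the per-beat SBP values whose
        ABP peak sample lies in the frame's interior (likewise DBP over
        trough samples); frames containing no peak or no trough get ``None``.
        Extrema on the first or last sample of a frame are not realized as
        local extrema within that frame, so they are excluded — this makes
        the reference an exact oracle for frame-wise label extraction on
        noise-free renders.
        """
        n_frames = n_samples // frame_len
        out: list[tuple[float, float] | None] = []
        for i in range(n_frames):
            lo, hi = i * frame_len, (i + 1) * frame_len
            pk = (self.abp_peak_indices > lo) & (self.abp_peak_indices < hi - 1)
            tr = (self.abp_trough_indices > lo) & (self.abp_trough_indices < hi - 1)
            if pk.any() and tr.any():
                out.append((float(self.per_beat_sbp[pk].mean()),
                            float(self.per_beat_dbp[tr].mean())))
            else:
                out.append(None)
        return out


def _draw_beats(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Beat times and instantaneous HR, first beat at half a mean RR."""
    mean_rr = 60.0 / cfg.hr_bpm
    times: list[float] = []
    hrs: list[float] = []
    t = 0.5 * mean_rr
    # leave room for the T wave of the final beat
    while t < cfg.duration_s - 0.3:
        hr = cfg.hr_bpm if cfg.hr_sd == 0 else float(np.clip(
            cfg.hr_bpm + cfg.hr_sd * rng.standard_normal(), 30.0, 220.0))
        times.append(t)
        hrs.append(hr)
        t += 60.0 / hr
    if not times:
        raise ConfigError(
            f"duration {cfg.duration_s} s too short for one beat at {cfg.hr_bpm} bpm")
    return np.asarray(times), np.asarray(hrs)


def _ecg_template(t: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    """Sum of Gaussian P/Q/R/S/T waves per beat.

    Wave timing and width scale with sqrt(RR) (Bazett-style rate adaptation:
    the QT interval and wave spacing shorten as heart rate rises), so beat
    morphology itself carries instantaneous-rate information just as real
    ECG does.
    """
    ecg = np.zeros_like(t)
    if beat_times.size > 1:
        rr = np.diff(beat_times)
        rr = np.append(rr, rr[-1])
    else:
        rr = np.ones_like(beat_times)
    scale = np.sqrt(np.clip(rr, 0.3, 2.0))
    for offset, amp, width in _ECG_WAVES:
        for c0, s in zip(beat_times, scale):
            c = c0 + offset * s
            w = width * s
            lo = np.searchsorted(t, c - 5 * w)
            hi = np.searchsorted(t, c + 5 * w)
            ecg[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / w) ** 2)
    return ecg


def simulate_ecg(config: SyntheticConfig) -> tuple[WaveformRecord, GroundTruth]:
    """Generate the ECG channel and its beat-time ground truth.

    The clean signal is a sum of five Gaussian waves per beat around an
    isoelectric level of 0 mV; broadband noise, power-line interference and
    baseline wander are added per config.
    """
    rng = np.random.default_rng(config.seed)
    beat_times, hrs = _draw_beats(config, rng)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    ecg = _ecg_template(t, beat_times)
    if config.noise_sd > 0:
        ecg = ecg + config.noise_sd * rng.standard_normal(n)
    if config.powerline_amp > 0:
        ecg = ecg + config.powerline_amp * np.sin(2 * np.pi * config.powerline_hz * t)
    if config.wander_amp > 0:
        ecg = ecg + config.wander_amp * np.sin(2 * np.pi * config.wander_hz * t)
    record = WaveformRecord(
        record_id=f"synth-{config.seed}",
        fs=config.fs,
        channels={"ecg": ecg},
        units={"ecg": "mV"},
    )
    truth = GroundTruth(beat_times_s=beat_times, fs=config.fs)
    truth._hrs = hrs  # instantaneous HR per beat, reused by simulate_abp
    return record, truth


def _per_beat_pressures(cfg: SyntheticConfig, truth: GroundTruth,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    hrs = getattr(truth, "_hrs", None)
    if hrs is None:
        rr = np.diff(truth.beat_times_s)
        hrs = 60.0 / np.concatenate([rr, rr[-1:]]) if rr.size else np.full(1, cfg.hr_bpm)
    if cfg.coupling is not None:
        a, b = cfg.coupling
        sbp = a + b * np.asarray(hrs)
    else:
        sbp = np.full(truth.n_beats, cfg.sbp_mmHg)
    if cfg.bp_drift > 0:
        # one slow cycle per record
        sbp = sbp + cfg.bp_drift * np.sin(2 * np.pi * truth.beat_times_s / cfg.duration_s)
    if cfg.coupling_noise_sd > 0:
        sbp = sbp + cfg.coupling_noise_sd * rng.standard_normal(truth.n_beats)
    pp = np.full(truth.n_beats, cfg.pulse_pressure)
    if cfg.pulse_pressure_sd > 0:
        pp = pp + cfg.pulse_pressure_sd * rng.standard_normal(truth.n_beats)
    pp = np.clip(pp, 10.0, None)  # keep SBP > DBP for every beat
    return sbp, sbp - pp


def simulate_abp(config: SyntheticConfig, truth: GroundTruth) -> WaveformRecord:
    """Render the ABP channel for the beats in ``truth`` (updated in place).

    Each cycle is a raised-cosine systolic upstroke followed by an
    exponential diastolic decay, constructed in the sample domain so the
    peak sample equals the beat's SBP and the onset sample its DBP exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xAB9]))
    sbp, dbp = _per_beat_pressures(config, truth, rng)
    n = int(round(config.duration_s * config.fs))
    abp = np.empty(n)

    onset = np.rint((truth.beat_times_s + _ABP_ONSET_DELAY_S) * config.fs).astype(int)
    onset = np.clip(onset, 0, n - 1)
    next_onset = np.concatenate([onset[1:], [n]])
    peak = onset + np.maximum(2, np.rint(_SYSTOLIC_PEAK_FRAC * (next_onset - onset)).astype(int))
    peak = np.minimum(peak, next_onset - 1)

    # lead-in before the first onset: decay toward dbp[0]
    if onset[0] > 0:
        s = np.linspace(0.3, 1.0, onset[0], endpoint=False)
        top = dbp[0] + 0.6 * (sbp[0] - dbp[0])
        abp[:onset[0]] = dbp[0] + (top - dbp[0]) * (np.exp(-_DECAY_TAU * s) - np.exp(-_DECAY_TAU)) / (
            1 - np.exp(-_DECAY_TAU))

    for k in range(truth.n_beats):
        i0, ip, i1 = onset[k], peak[k], next_onset[k]
        end_dbp = dbp[k + 1] if k + 1 < truth.n_beats else dbp[k]
        # raised-cosine upstroke: exactly dbp at i0, exactly sbp at ip
        m = ip - i0
        u = np.arange(m + 1) / m
        abp[i0:ip + 1] = dbp[k] + (sbp[k] - dbp[k]) * 0.5 * (1 - np.cos(np.pi * u))
        # exponential decay from sbp at ip down to the next onset's dbp
        mdec = i1 - ip
        if mdec > 1:
            s = np.arange(1, mdec) / mdec
            abp[ip + 1:i1] = end_dbp + (sbp[k] - end_dbp) * (
                np.exp(-_DECAY_TAU * s) - np.exp(-_DECAY_TAU)) / (1 - np.exp(-_DECAY_TAU))

    truth.per_beat_sbp = sbp
    truth.per_beat_dbp = dbp
    truth.abp_peak_indices = peak
    truth.abp_trough_indices = onset
    return WaveformRecord(
        record_id=f"synth-{config.seed}",
        fs=config.fs,
        channels={"abp": abp},
        units={"abp": "mmHg"},
    )


def simulate_record(config: SyntheticConfig) -> tuple[WaveformRecord, GroundTruth]:
    """Generate one paired two-channel (ecg, abp) record with ground truth."""
    ecg_rec, truth = simulate_ecg(config)
    abp_rec = simulate_abp(config, truth)
    record = WaveformRecord(
        record_id=ecg_rec.record_id,
        fs=config.fs,
        channels={"ecg": ecg_rec.channels["ecg"], "abp": abp_rec.channels["abp"]},
        units={"ecg": "mV", "abp": "mmHg"},
    )
    return record, truth


def simulate_dataset(
    config: SyntheticConfig,
    n_records: int,
    hr_jitter_sd: float = 10.0,
    pp_jitter_sd: float = 3.0,
) -> list[tuple[WaveformRecord, GroundTruth]]:
    """Generate ``n_records`` independent records with jittered baselines.

    Per-record jitter emulates between-patient variation: the record's mean
    heart rate is ``hr_bpm + N(0, hr_jitter_sd)`` (clipped to [45, 140] bpm)
    and its pulse pressure is ``pulse_pressure + N(0, pp_jitter_sd)`` (clipped
    to >= 20 mmHg).  Record seeds derive deterministically from the master
    ``config.seed``, so regeneration reproduces the whole dataset.
    """
    if n_records < 1:
        raise ConfigError("n_records must be >= 1")
    master = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xD5]))
    out = []
    for i in range(n_records):
        hr = float(np.clip(config.hr_bpm + hr_jitter_sd * master.standard_normal(), 45.0, 140.0))
        pp = float(np.clip(config.pulse_pressure + pp_jitter_sd * master.standard_normal(), 20.0, None))
        sub = replace(
            config,
            hr_bpm=hr,
            dbp_mmHg=config.sbp_mmHg - pp,
            seed=int((config.seed * 100003 + i) % (2**31 - 1)),
        )
        rec, truth = simulate_record(sub)
        rec.record_id = f"synth-{config.seed}-{i:03d}"
        out.append((rec, truth))
    return out
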