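"""SBP/DBP label extraction from ABP frames and ECG rhythm analysis.

Training targets come from the arterial-pressure channel: systolic peaks and
diastolic troughs are located per frame and their mean amplitudes become the
frame's (SBP, DBP) label, mirroring how reference pressures are read off an
invasive ABP line.  The rhythm side provides a classic energy-transform QRS
detector (derivative -> squaring -> moving-window integration -> adaptive
threshold) plus RR-interval / heart-rate summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, SchemaError
from .preprocess import FramePair
from .signal_io import BeatAnnotation

#: default minimum spacing between ABP extrema of the same kind, seconds
ABP_REFRACTORY_S = 0.3
#: default extrema prominence floor, as a fraction of the frame's dynamic range
PROMINENCE_FRAC = 0.1
#: QRS refractory period, seconds
QRS_REFRACTORY_S = 0.25

# Plausibility bounds for a trainable label (configurable in label_frames)
SBP_MAX = 250.0
DBP_MIN = 20.0


@dataclass
class BPLabel:
    """Frame-level blood-pressure label in mmHg.

    ``valid`` is False when the frame contains no usable systolic peak or
    diastolic trough, or the extracted pressures are physiologically
    implausible; invalid frames are excluded from training.
    """

    sbp: float
    dbp: float
    n_peaks: int
    n_troughs: int
    valid: bool = True


@dataclass
class RhythmSummary:
    """RR intervals and heart rate derived from R-peak annotations."""

    r_peaks: BeatAnnotation
    rr_s: np.ndarray           # rr_s[i] = (peak[i+1] - peak[i]) / fs
    hr_bpm: np.ndarray         # instantaneous, 60 / rr_s
    mean_hr_bpm: float


def _alternate(peaks: np.ndarray, troughs: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enforce strict peak/trough alternation.

    Among consecutive extrema of the same kind, keep the most extreme one.
    """
    events = sorted(
        [(i, 1) for i in peaks] + [(i, -1) for i in troughs])
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = x[idx] > x[prev] if kind == 1 else x[idx] < x[prev]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    p = np.array([i for i, k in kept if k == 1], dtype=int)
    t = np.array([i for i, k in kept if k == -1], dtype=int)
    return p, t


def find_abp_extrema(
    abp: np.ndarray,
    fs: float,
    refractory_s: float = ABP_REFRACTORY_S,
    prominence_frac: float = PROMINENCE_FRAC,
) -> tuple[BeatAnnotation, BeatAnnotation]:
    """Locate systolic peaks and diastolic troughs in an ABP segment.

    Peaks/troughs must be separated by at least ``refractory_s``, and must
    clear an amplitude dead-band around the segment midrange: systolic peaks
    lie at least ``prominence_frac * range / 2`` above the midrange value,
    diastolic troughs the same margin below it.  Amplitude gating (rather
    than scipy peak prominence) stays reliable for extrema close to a frame
    boundary, where a truncated flank makes measured prominence collapse.
    The two series are forced to alternate.  A flat segment (zero dynamic
    range) yields empty annotations — the degenerate-signal case.
    """
    abp = np.asarray(abp, dtype=float)
    dyn = float(np.ptp(abp))
    n = abp.size
    if dyn <= 1e-9:
        empty_p = BeatAnnotation(np.empty(0, dtype=int), "abp_peak", n)
        empty_t = BeatAnnotation(np.empty(0, dtype=int), "abp_trough", n)
        return empty_p, empty_t
    distance = max(1, int(round(refractory_s * fs)))
    mid = float(np.min(abp)) + 0.5 * dyn
    band = 0.5 * prominence_frac * dyn
    peaks, _ = sps.find_peaks(abp, distance=distance, height=mid + band)
    troughs, _ = sps.find_peaks(-abp, distance=distance, height=-(mid - band))
    peaks, troughs = _alternate(peaks, troughs, abp)
    return (BeatAnnotation(peaks, "abp_peak", n),
            BeatAnnotation(troughs, "abp_trough", n))


def label_frame(
    frame: FramePair,
    fs: float,
    sbp_max: float = SBP_MAX,
    dbp_min: float = DBP_MIN,
) -> BPLabel:
    """Average the frame's systolic-peak and diastolic-trough amplitudes.

    The frame label is (mean peak amplitude, mean trough amplitude) in mmHg.
    A 128-sample frame at 125 Hz spans ~1.02 s and may contain 1-2 beats;
    whatever extrema exist are averaged.  Frames with no extrema, inverted
    pressures (SBP <= DBP) or implausible values are flagged invalid.
    """
    if frame.abp is None:
        raise SchemaError(f"frame {frame.frame_index} has no abp channel to label")
    peaks, troughs = find_abp_extrema(frame.abp, fs)
    if len(peaks) == 0 or len(troughs) == 0:
        return BPLabel(np.nan, np.nan, len(peaks), len(troughs), valid=False)
    sbp = float(frame.abp[peaks.indices].mean())
    dbp = float(frame.abp[troughs.indices].mean())
    valid = sbp > dbp and sbp <= sbp_max and dbp >= dbp_min
    return BPLabel(sbp, dbp, len(peaks), len(troughs), valid=valid)


def label_frames(frames: list[FramePair], fs: float, **kwargs) -> list[BPLabel]:
    """Label a list of frames; convenience wrapper over :func:`label_frame`."""
    return [label_frame(f, fs, **kwargs) for f in frames]


def detect_qrs(ecg: np.ndarray, fs: float, refractory_s: float = QRS_REFRACTORY_S) -> BeatAnnotation:
    """R-peak detection by the classic energy-transform recipe.

    Band-pass (5-15 Hz) -> derivative -> squaring -> 150 ms moving-window
    integration, then an adaptive signal/noise threshold with a refractory
    period.  Each detection is refined to the local ECG maximum within
    +/-100 ms, so reported indices sit on the R wave itself.
    """
    ecg = np.asarray(ecg, dtype=float)
    n = ecg.size
    if n < int(0.5 * fs) or np.ptp(ecg) <= 1e-9:
        warnings.warn("signal too short or flat for QRS detection", stacklevel=2)
        return BeatAnnotation(np.empty(0, dtype=int), "r_peak", n)

    sos = sps.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(band)
    energy = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")

    distance = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(mwi, distance=distance)
    if cand.size == 0:
        warnings.warn("no QRS energy peaks found", stacklevel=2)
        return BeatAnnotation(np.empty(0, dtype=int), "r_peak", n)

    # adaptive running threshold (signal vs noise peak estimates)
    spk = float(np.max(mwi[: min(n, int(2 * fs))]) * 0.6)
    npk = float(np.mean(mwi[: min(n, int(2 * fs))]) * 0.5)
    accepted: list[int] = []
    for c in cand:
        thr = npk + 0.25 * (spk - npk)
        if mwi[c] > thr:
            spk = 0.125 * mwi[c] + 0.875 * spk
            accepted.append(c)
        else:
            npk = 0.125 * mwi[c] + 0.875 * npk

    # refine each detection to the local ECG maximum (R wave apex)
    half = int(round(0.100 * fs))
    r_peaks = []
    for c in accepted:
        lo, hi = max(0, c - half), min(n, c + half + 1)
        r_peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    r = np.unique(np.asarray(r_peaks, dtype=int))
    # refinement can merge neighbours; enforce the refractory spacing
    if r.size > 1:
        keep = [0]
        for i in range(1, r.size):
            if r[i] - r[keep[-1]] >= distance:
                keep.append(i)
            elif ecg[r[i]] > ecg[r[keep[-1]]]:
                keep[-1] = i
        r = r[keep]
    if r.size == 0:
        warnings.warn("no beats found", stacklevel=2)
    return BeatAnnotation(r, "r_peak", n)


def rhythm_summary(annotation: BeatAnnotation, fs: float) -> RhythmSummary:
    """RR intervals (s) and instantaneous heart rate (bpm) from R peaks."""
    if len(annotation) < 2:
        raise InsufficientDataError(
            f"need >= 2 R-peaks for RR intervals, got {len(annotation)}")
    rr = np.diff(annotation.indices) / fs
    hr = 60.0 / rr
    return RhythmSummary(r_peaks=annotation, rr_s=rr, hr_bpm=hr,
                         mean_hr_bpm=float(hr.mean()))
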