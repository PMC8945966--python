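"""Signal conditioning and fixed-length segmentation.

The conditioning chain applied to the ECG channel before modelling is:

1. zero-phase low-pass filtering (4th-order Butterworth at 50 Hz, applied
   forward-backward so R-peak timing is not shifted);
2. wavelet baseline-drift removal: a multilevel Daubechies-4 decomposition
   whose depth is chosen from the sampling rate so the approximation band
   lies below ~0.5 Hz; the approximation coefficients are zeroed before
   reconstruction, removing respiration/electrode drift while preserving the
   QRS band;
3. segmentation into non-overlapping frames of 128 samples (~1.02 s at
   125 Hz); the trailing remainder shorter than one frame is discarded.

The ABP channel is left unfiltered by default: its per-cycle extrema are the
label source and must not be attenuated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .errors import AlignmentError, ParameterError, SchemaError
from .signal_io import WaveformRecord

FRAME_LEN = 128


@dataclass
class FramePair:
    """One fixed-length ECG window with its aligned ABP window.

    ``abp`` may be ``None`` at inference time (no reference pressure
    available).  Frames tile the source signal without overlap, so
    ``start_sample == frame_index * len(ecg)``.
    """

    ecg: np.ndarray
    abp: np.ndarray | None
    frame_index: int
    source_record: str = ""
    start_sample: int = 0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        if self.abp is not None:
            self.abp = np.asarray(self.abp, dtype=float)
            if self.abp.shape != self.ecg.shape:
                raise AlignmentError(
                    f"frame {self.frame_index}: ecg has {self.ecg.size} samples, "
                    f"abp has {self.abp.size}")

    @property
    def frame_len(self) -> int:
        return self.ecg.size


@dataclass
class PreprocessConfig:
    """Options of the conditioning chain.

    ``wavelet_level=None`` selects the depth from the sampling rate
    (smallest level whose approximation band edge ``fs / 2**(level+1)`` is at
    or below ``drift_edge_hz``).  ``filter_abp`` applies the same chain to the
    ABP channel; off by default so label extrema stay untouched.
    """

    cutoff_hz: float = 50.0
    filter_order: int = 4
    wavelet: str = "db4"
    wavelet_level: int | None = None
    drift_edge_hz: float = 0.5
    frame_len: int = FRAME_LEN
    filter_abp: bool = False
    remove_baseline: bool = True


def lowpass_filter(x: np.ndarray, fs: float, cutoff: float = 50.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass.

    Applied forward-backward (``filtfilt``), so the effective magnitude
    response is the squared Butterworth magnitude and the phase is zero —
    fiducial points do not shift.
    """
    if fs <= 2 * cutoff:
        raise ParameterError(f"fs={fs} Hz must exceed twice the {cutoff} Hz cut-off")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ParameterError(f"signal of {x.size} samples too short for the filter warm-up")
    return sps.sosfiltfilt(sos, x)


def baseline_level_for_fs(fs: float, drift_edge_hz: float = 0.5) -> int:
    """Decomposition depth whose approximation band edge is <= drift_edge_hz."""
    return max(1, math.ceil(math.log2(fs / drift_edge_hz)) - 1)


def remove_baseline_wavelet(
    x: np.ndarray,
    fs: float,
    wavelet: str = "db4",
    level: int | None = None,
    drift_edge_hz: float = 0.5,
) -> np.ndarray:
    """Suppress sub-``drift_edge_hz`` baseline drift by wavelet decomposition.

    The signal is decomposed to ``level`` (fs-aware default), the
    lowest-frequency approximation is zeroed, and the detail bands are
    reconstructed.  DC offsets live entirely in the approximation band, so
    the output is approximately zero-mean.
    """
    x = np.asarray(x, dtype=float)
    if level is None:
        level = baseline_level_for_fs(fs, drift_edge_hz)
    if x.size < 2 ** level:
        raise ParameterError(
            f"signal of {x.size} samples too short for a level-{level} decomposition")
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        level = max_level
    coeffs = pywt.wavedec(x, wavelet, level=level)
    coeffs[0] = np.zeros_like(coeffs[0])
    out = pywt.waverec(coeffs, wavelet)
    return out[: x.size]


def segment_pair(
    ecg: np.ndarray,
    abp: np.ndarray | None,
    frame_len: int = FRAME_LEN,
    source_record: str = "",
) -> list[FramePair]:
    """Tile paired signals into non-overlapping ``frame_len`` windows.

    Yields ``floor(n / frame_len)`` frames; the trailing remainder is
    discarded.  ECG and ABP frames share start samples.
    """
    ecg = np.asarray(ecg, dtype=float)
    if abp is not None:
        abp = np.asarray(abp, dtype=float)
        if abp.size != ecg.size:
            raise AlignmentError(f"ecg has {ecg.size} samples but abp has {abp.size}")
    n_frames = ecg.size // frame_len
    if n_frames == 0:
        warnings.warn(
            f"signal of {ecg.size} samples shorter than one {frame_len}-sample frame; "
            "no frames produced", stacklevel=2)
        return []
    frames = []
    for i in range(n_frames):
        lo = i * frame_len
        frames.append(FramePair(
            ecg=ecg[lo:lo + frame_len].copy(),
            abp=None if abp is None else abp[lo:lo + frame_len].copy(),
            frame_index=i,
            source_record=source_record,
            start_sample=lo,
        ))
    return frames


def preprocess_record(record: WaveformRecord, opts: PreprocessConfig | None = None) -> list[FramePair]:
    """Condition a record's ECG (and optionally ABP) and segment both channels.

    The ECG channel is low-pass filtered then baseline-corrected; the ABP
    channel passes through unfiltered unless ``opts.filter_abp`` is set,
    because SBP/DBP labels are read from its raw extrema.
    """
    opts = opts or PreprocessConfig()
    if "ecg" not in record.channels:
        raise SchemaError(f"record {record.record_id!r} has no 'ecg' channel "
                          f"(channels: {record.channel_names})")
    ecg = lowpass_filter(record.channels["ecg"], record.fs, opts.cutoff_hz, opts.filter_order)
    if opts.remove_baseline:
        ecg = remove_baseline_wavelet(ecg, record.fs, opts.wavelet,
                                      opts.wavelet_level, opts.drift_edge_hz)
    abp = record.channels.get("abp")
    if abp is not None and opts.filter_abp:
        abp = lowpass_filter(abp, record.fs, opts.cutoff_hz, opts.filter_order)
    return segment_pair(ecg, abp, opts.frame_len, source_record=record.record_id)
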