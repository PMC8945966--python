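"""HDF5 storage for segmented frames and their labels."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .labeling import BPLabel
from .preprocess import FramePair


def save_frames(
    path: str | Path,
    frames: Sequence[FramePair],
    fs: float,
    labels: Sequence[BPLabel] | None = None,
) -> Path:
    """Write frames (and optional labels) to one HDF5 file."""
    path = Path(path)
    n = len(frames)
    frame_len = frames[0].frame_len if n else 0
    has_abp = np.array([f.abp is not None for f in frames], dtype=bool)
    with h5py.File(path, "w") as h5:
        h5.attrs["fs"] = fs
        h5.attrs["frame_len"] = frame_len
        h5.create_dataset("ecg", data=np.asarray([f.ecg for f in frames]))
        abp = np.full((n, frame_len), np.nan)
        for i, f in enumerate(frames):
            if f.abp is not None:
                abp[i] = f.abp
        h5.create_dataset("abp", data=abp)
        h5.create_dataset("has_abp", data=has_abp)
        h5.create_dataset("frame_index", data=np.asarray([f.frame_index for f in frames]))
        h5.create_dataset("start_sample", data=np.asarray([f.start_sample for f in frames]))
        h5.create_dataset(
            "source_record",
            data=np.asarray([f.source_record for f in frames], dtype=h5py.string_dtype()))
        if labels is not None:
            g = h5.create_group("labels")
            g.create_dataset("sbp", data=np.asarray([l.sbp for l in labels]))
            g.create_dataset("dbp", data=np.asarray([l.dbp for l in labels]))
            g.create_dataset("n_peaks", data=np.asarray([l.n_peaks for l in labels]))
            g.create_dataset("n_troughs", data=np.asarray([l.n_troughs for l in labels]))
            g.create_dataset("valid", data=np.asarray([l.valid for l in labels], dtype=bool))
    return path


def load_frames(path: str | Path) -> tuple[list[FramePair], float, list[BPLabel] | None]:
    """Read frames (and labels, if present) back; returns (frames, fs, labels)."""
    with h5py.File(path, "r") as h5:
        fs = float(h5.attrs["fs"])
        ecg = h5["ecg"][:]
        abp = h5["abp"][:]
        has_abp = h5["has_abp"][:]
        fidx = h5["frame_index"][:]
        start = h5["start_sample"][:]
        src = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["source_record"][:]]
        frames = [
            FramePair(
                ecg=ecg[i],
                abp=abp[i] if has_abp[i] else None,
                frame_index=int(fidx[i]),
                source_record=src[i],
                start_sample=int(start[i]),
            )
            for i in range(len(ecg))
        ]
        labels = None
        if "labels" in h5:
            g = h5["labels"]
            labels = [
                BPLabel(float(g["sbp"][i]), float(g["dbp"][i]),
                        int(g["n_peaks"][i]), int(g["n_troughs"][i]),
                        bool(g["valid"][i]))
                for i in range(len(ecg))
            ]
    return frames, fs, labels
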