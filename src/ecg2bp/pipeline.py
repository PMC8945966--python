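"""End-to-end pipeline orchestration and run configuration.

A :class:`RunConfig` describes one reproducible experiment: where the input
records come from (files or the synthetic generator), how they are
conditioned and segmented, the network and optimization hyperparameters, and
the evaluation thresholds.  ``run_pipeline`` executes
simulate/load -> preprocess -> label -> split -> train -> evaluate and writes
all artifacts (frames, model, history, report, frozen config) under one run
directory.  A single master seed deterministically derives every stage seed,
so a rerun with the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigError, SchemaError
from .evaluate import AAMI_THRESHOLDS, evaluate_model, plot_report
from .frames_io import save_frames
from .labeling import label_frames
from .model import ModelConfig, TrainConfig, build_model, train, save_model
from .preprocess import PreprocessConfig, preprocess_record
from .signal_io import read_record
from .synth import SyntheticConfig, simulate_dataset

log = logging.getLogger("ecg2bp")


class SynthBlock(BaseModel):
    n_records: int = Field(default=8, ge=1)
    duration_s: float = Field(default=60.0, gt=0)
    fs: float = Field(default=125.0, gt=0)
    hr_bpm: float = Field(default=75.0, gt=0)
    hr_sd: float = Field(default=2.0, ge=0)
    sbp_mmHg: float = 120.0
    dbp_mmHg: float = 80.0
    bp_drift: float = Field(default=2.0, ge=0)
    coupling: Optional[tuple[float, float]] = (90.0, 0.5)
    coupling_noise_sd: float = Field(default=2.0, ge=0)
    pulse_pressure_sd: float = Field(default=2.0, ge=0)
    noise_sd: float = Field(default=0.05, ge=0)
    powerline_hz: float = 60.0
    powerline_amp: float = Field(default=0.02, ge=0)
    wander_hz: float = 0.2
    wander_amp: float = Field(default=0.1, ge=0)
    hr_jitter_sd: float = Field(default=10.0, ge=0)
    pp_jitter_sd: float = Field(default=3.0, ge=0)

    @model_validator(mode="after")
    def _bp_ordered(self):
        if self.sbp_mmHg <= self.dbp_mmHg:
            raise ValueError("synth.sbp_mmHg must exceed synth.dbp_mmHg")
        return self


class PreprocessBlock(BaseModel):
    cutoff_hz: float = Field(default=50.0, gt=0)
    filter_order: int = Field(default=4, ge=1)
    wavelet: str = "db4"
    wavelet_level: Optional[int] = None
    drift_edge_hz: float = Field(default=0.5, gt=0)
    frame_len: int = Field(default=128, ge=16)
    filter_abp: bool = False
    remove_baseline: bool = True


class ModelBlock(BaseModel):
    conv_filters: tuple[int, int, int, int] = (32, 64, 128, 256)
    kernel_size: int = Field(default=7, ge=1)
    pool_size: int = Field(default=2, ge=2)
    feature_dim: int = Field(default=128, ge=1)
    fc_nodes: tuple[int, int] = (32, 16)
    input_norm: bool = True


class TrainBlock(BaseModel):
    batch_size: int = Field(default=32, ge=1)
    learning_rate: float = Field(default=0.01, gt=0)
    max_epochs: int = Field(default=200, ge=1)
    patience: int = Field(default=20, ge=1)
    split_fraction: float = Field(default=0.8, gt=0, lt=1)
    split_mode: str = Field(default="frame", pattern="^(frame|record)$")
    standardize_targets: bool = True
    grad_clip: Optional[float] = 5.0


class EvaluateBlock(BaseModel):
    aami_me_mmHg: float = Field(default=AAMI_THRESHOLDS[0], gt=0)
    aami_sd_mmHg: float = Field(default=AAMI_THRESHOLDS[1], gt=0)
    plots: bool = True


class RunConfig(BaseModel):
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs"
    run_name: Optional[str] = None
    input_records: list[str] = Field(default_factory=list)
    synth: Optional[SynthBlock] = None
    preprocess: PreprocessBlock = Field(default_factory=PreprocessBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    evaluate: EvaluateBlock = Field(default_factory=EvaluateBlock)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _cross_field(self):
        if not self.input_records and self.synth is None:
            raise ValueError("config needs an 'input_records' list or a 'synth' block")
        if self.preprocess.frame_len % self.model.pool_size ** 4 != 0:
            raise ValueError(
                f"preprocess.frame_len={self.preprocess.frame_len} is not divisible "
                f"by model.pool_size^4={self.model.pool_size ** 4}")
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load, schema-check and default-fill a JSON run config.

    Raises :class:`ConfigError` listing every violation with its field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} not found")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    return validate_config_dict(data)


def validate_config_dict(data: dict) -> RunConfig:
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError("invalid run config:\n  " + "\n  ".join(msgs)) from exc


def _derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return int((master * 1_000_003 + h) % (2**31 - 1))


def run_pipeline(config: RunConfig, run_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline described by ``config``; returns the run directory.

    Artifacts written: ``config.json`` (frozen resolved config + package
    version), ``frames.h5``, ``model/``, ``history.json``, ``report.json``,
    optional agreement plots, and ``run.log``.
    """
    t_start = time.time()
    if run_dir is None:
        name = config.run_name or time.strftime("run-%Y%m%d-%H%M%S")
        run_dir = Path(config.out_dir) / name
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        from . import __version__ as _pkg_version
        frozen = {"config": config.model_dump(mode="json"), "version": _pkg_version}
        (run_dir / "config.json").write_text(json.dumps(frozen, indent=2, sort_keys=True))

        # ---- stage 1: acquire records -----------------------------------
        records = []
        if config.synth is not None:
            sb = config.synth
            syn_cfg = SyntheticConfig(
                duration_s=sb.duration_s, fs=sb.fs, hr_bpm=sb.hr_bpm, hr_sd=sb.hr_sd,
                sbp_mmHg=sb.sbp_mmHg, dbp_mmHg=sb.dbp_mmHg, bp_drift=sb.bp_drift,
                coupling=sb.coupling, coupling_noise_sd=sb.coupling_noise_sd,
                pulse_pressure_sd=sb.pulse_pressure_sd, noise_sd=sb.noise_sd,
                powerline_hz=sb.powerline_hz, powerline_amp=sb.powerline_amp,
                wander_hz=sb.wander_hz, wander_amp=sb.wander_amp,
                seed=_derive_seed(config.seed, "synth"),
            )
            records = [rec for rec, _ in simulate_dataset(
                syn_cfg, sb.n_records, sb.hr_jitter_sd, sb.pp_jitter_sd)]
            log.info("simulated %d records of %.0f s at %.0f Hz",
                     len(records), sb.duration_s, sb.fs)
        for p in config.input_records:
            fmt = "wfdb" if str(p).endswith((".hea", ".dat")) else "csv"
            records.append(read_record(p, format=fmt))
        if not records:
            raise SchemaError("no input records")
        fs = records[0].fs

        # ---- stage 2: preprocess + segment ------------------------------
        pb = config.preprocess
        popts = PreprocessConfig(
            cutoff_hz=pb.cutoff_hz, filter_order=pb.filter_order, wavelet=pb.wavelet,
            wavelet_level=pb.wavelet_level, drift_edge_hz=pb.drift_edge_hz,
            frame_len=pb.frame_len, filter_abp=pb.filter_abp,
            remove_baseline=pb.remove_baseline)
        frames = []
        for rec in records:
            frames.extend(preprocess_record(rec, popts))
        log.info("segmented %d frames of %d samples", len(frames), pb.frame_len)

        # ---- stage 3: label ---------------------------------------------
        labels = label_frames(frames, fs)
        n_valid = sum(l.valid for l in labels)
        log.info("labeled frames: %d valid / %d total", n_valid, len(labels))
        save_frames(run_dir / "frames.h5", frames, fs, labels)

        # ---- stage 4: train ---------------------------------------------
        mb = config.model
        mcfg = ModelConfig(
            frame_len=pb.frame_len, conv_filters=mb.conv_filters,
            kernel_size=mb.kernel_size, pool_size=mb.pool_size,
            feature_dim=mb.feature_dim, fc_nodes=mb.fc_nodes,
            input_norm=mb.input_norm)
        tb = config.train
        tcfg = TrainConfig(
            batch_size=tb.batch_size, learning_rate=tb.learning_rate,
            max_epochs=tb.max_epochs, patience=tb.patience,
            split_fraction=tb.split_fraction, split_mode=tb.split_mode,
            standardize_targets=tb.standardize_targets, grad_clip=tb.grad_clip,
            seed=_derive_seed(config.seed, "train"))
        model = build_model(mcfg, seed=_derive_seed(config.seed, "init"))
        model, history = train(model, frames, labels, tcfg)
        log.info("trained %d epochs; best epoch %d (val loss %.4g)",
                 history.n_epochs, history.best_epoch,
                 history.val_loss[history.best_epoch])
        save_model(model, run_dir / "model")
        (run_dir / "history.json").write_text(json.dumps(
            {"train_loss": history.train_loss, "val_loss": history.val_loss,
             "best_epoch": history.best_epoch}, indent=2))

        # ---- stage 5: evaluate on the held-out split --------------------
        valid_pairs = [(f, l) for f, l in zip(frames, labels) if l.valid]
        eval_pairs = [valid_pairs[i] for i in history.val_indices]
        report = evaluate_model(
            model, [f for f, _ in eval_pairs], [l for _, l in eval_pairs],
            aami_thresholds=(config.evaluate.aami_me_mmHg, config.evaluate.aami_sd_mmHg))
        report.to_json(run_dir / "report.json")
        if config.evaluate.plots:
            plot_report(report, run_dir / "plots")
        log.info("evaluation on %d held-out frames: SBP r=%s MAE=%.2f mmHg; "
                 "DBP r=%s MAE=%.2f mmHg",
                 report.n, report.sbp.pearson_r, report.sbp.mae,
                 report.dbp.pearson_r, report.dbp.mae)
        log.info("run complete in %.1f s", time.time() - t_start)
        return run_dir
    finally:
        log.removeHandler(handler)
        handler.close()
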