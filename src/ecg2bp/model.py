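"""The 1D-CNN blood-pressure regressor: architecture, training, persistence.

A 128-sample conditioned ECG frame is mapped to (SBP, DBP) in mmHg by a small
convolutional network:

    [conv(32, k=7, same) -> ReLU -> maxpool(2)]
    [conv(64)  -> ReLU -> pool] [conv(128) -> ReLU -> pool]
    [conv(256) -> ReLU -> pool]
    global-average-pool over time (-> 256)
    dense(128, ReLU)  -> dense(32, ReLU) -> dense(16, ReLU) -> dense(2, linear)

i.e. four convolutional layers each followed by a max-pooling layer
(128 -> 64 -> 32 -> 16 -> 8 time steps), a 128-unit learned-feature layer,
and two fully connected layers of 32 and 16 nodes feeding a linear 2-output
head.  The default kernel width of 7 gives the deepest layer a receptive
field of ~0.73 s at 125 Hz — wide enough to span one RR interval, the scale
at which rate information lives.

Training minimizes mean squared error on z-scored (SBP, DBP) targets with
Adam (batch size 32, initial learning rate 0.01 by default, with a short
linear warmup, gradient-norm clipping and plateau halving for stability);
the target z-score parameters are estimated on the training split only and
undone at prediction time.  Inputs are z-scored per frame by default to
remove electrode-gain differences.

The implementation is self-contained numpy (see ``_nn``): forward and
backward passes are exact, runs are deterministic under a fixed seed, and
the ~190k parameters train in seconds per epoch on one CPU at the data sizes
this package targets.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .errors import (
    ConfigError,
    DataError,
    DivergenceError,
    ModelPersistenceError,
    ShapeError,
)
from .labeling import BPLabel
from .preprocess import FramePair

_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The network has exactly four conv+pool stages; ``frame_len`` must be
    divisible by ``pool_size**4`` so each stage halves the time axis cleanly.
    """

    frame_len: int = 128
    conv_filters: tuple[int, int, int, int] = (32, 64, 128, 256)
    kernel_size: int = 7
    pool_size: int = 2
    feature_dim: int = 128
    fc_nodes: tuple[int, int] = (32, 16)
    input_norm: bool = True

    def __post_init__(self) -> None:
        self.conv_filters = tuple(self.conv_filters)
        self.fc_nodes = tuple(self.fc_nodes)
        if len(self.conv_filters) != 4:
            raise ConfigError("the architecture has exactly 4 conv layers")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ConfigError("kernel_size must be odd and positive")
        if self.frame_len % self.pool_size ** 4 != 0:
            raise ConfigError(
                f"frame_len={self.frame_len} not divisible by pool_size^4="
                f"{self.pool_size ** 4}")


@dataclass
class TrainConfig:
    """Optimization protocol.

    ``split_fraction`` of the valid frames train the network and the rest
    form the validation split used for early stopping; the split is disjoint
    and exhaustive.  ``split_mode`` is ``"frame"`` (pooled-frame random
    split) or ``"record"`` (all frames of a record stay on one side — avoids
    leaking record identity across the split).
    """

    batch_size: int = 32
    learning_rate: float = 0.01
    max_epochs: int = 200
    patience: int = 20
    split_fraction: float = 0.8
    split_mode: str = "frame"
    standardize_targets: bool = True
    grad_clip: float | None = 1.0
    warmup_epochs: int = 3       # linear LR ramp-up; protects ReLUs from early blowups
    lr_decay: float = 0.5        # multiply LR by this on a validation plateau
    lr_patience: int = 5         # epochs without improvement before decaying
    min_lr: float = 1e-4
    restore_best: bool = True    # return the best-val checkpoint (False: final params)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ConfigError("split_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("batch_size and max_epochs must be >= 1")
        if self.split_mode not in ("frame", "record"):
            raise ConfigError(f"unknown split_mode {self.split_mode!r}")


@dataclass
class TrainingHistory:
    """Per-epoch loss trace; ``best_epoch`` is the argmin of validation loss.

    ``train_indices`` / ``val_indices`` index into the list of *valid*
    labeled frames (in input order), recording the split actually used.
    """

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_indices: list[int] = field(default_factory=list)
    val_indices: list[int] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss)) if self.val_loss else -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class BPRegressor:
    """Model handle: parameters + config + target-scaling state."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        c_in = 1
        for i, f in enumerate(config.conv_filters):
            fan_in = c_in * config.kernel_size
            p[f"conv{i}_W"] = (rng.standard_normal((f, c_in, config.kernel_size))
                               * np.sqrt(2.0 / fan_in)).astype(np.float32)
            p[f"conv{i}_b"] = np.zeros(f, dtype=np.float32)
            c_in = f
        dims = [config.conv_filters[-1], config.feature_dim, *config.fc_nodes, 2]
        for i in range(len(dims) - 1):
            p[f"fc{i}_W"] = (rng.standard_normal((dims[i], dims[i + 1]))
                             * np.sqrt(2.0 / dims[i])).astype(np.float32)
            p[f"fc{i}_b"] = np.zeros(dims[i + 1], dtype=np.float32)
        self.params = p
        # target z-score parameters (identity until fitted)
        self.target_mean = np.zeros(2)
        self.target_std = np.ones(2)

    # -- forward / backward -------------------------------------------------

    def _normalize_input(self, X: np.ndarray) -> np.ndarray:
        if not self.config.input_norm:
            return X
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        return (X - mu) / np.maximum(sd, 1e-8)

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """X: (N, frame_len) raw frames -> standardized (N, 2) outputs."""
        if X.ndim != 2 or X.shape[1] != self.config.frame_len:
            raise ShapeError(
                f"expected (N, {self.config.frame_len}) input, got {X.shape}")
        x = self._normalize_input(np.asarray(X, dtype=float)).astype(np.float32)[:, None, :]
        caches = []
        for i in range(4):
            x, c_conv = _nn.conv1d_forward(x, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"])
            x, c_relu = _nn.relu_forward(x)
            x, c_pool = _nn.maxpool_forward(x, self.config.pool_size)
            caches.append((c_conv, c_relu, c_pool))
        x, c_gap = _nn.gap_forward(x)
        caches.append(c_gap)
        n_fc = 2 + len(self.config.fc_nodes)  # feature layer + hidden FCs
        for i in range(n_fc):
            x, c_fc = _nn.dense_forward(x, self.params[f"fc{i}_W"], self.params[f"fc{i}_b"])
            if i < n_fc - 1:
                x, c_r = _nn.relu_forward(x)
            else:
                c_r = None  # linear head
            caches.append((c_fc, c_r))
        return (x, caches) if want_cache else x

    def backward(self, dout: np.ndarray, caches) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        n_fc = 2 + len(self.config.fc_nodes)
        d = dout
        for i in reversed(range(n_fc)):
            c_fc, c_r = caches[4 + 1 + i]
            if c_r is not None:
                d = _nn.relu_backward(d, c_r)
            d, grads[f"fc{i}_W"], grads[f"fc{i}_b"] = _nn.dense_backward(
                d, self.params[f"fc{i}_W"], c_fc)
        d = _nn.gap_backward(d, caches[4])
        for i in reversed(range(4)):
            c_conv, c_relu, c_pool = caches[i]
            d = _nn.maxpool_backward(d, c_pool)
            d = _nn.relu_backward(d, c_relu)
            d, grads[f"conv{i}_W"], grads[f"conv{i}_b"] = _nn.conv1d_backward(
                d, self.params[f"conv{i}_W"], c_conv)
        return grads

    def predict_mmhg(self, X: np.ndarray) -> np.ndarray:
        """Raw frames (N, frame_len) -> de-standardized (N, 2) [SBP, DBP] mmHg."""
        return self.forward(X) * self.target_std + self.target_mean

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


def build_model(config: ModelConfig | None = None, seed: int = 0) -> BPRegressor:
    """Construct a freshly initialized network (deterministic under seed)."""
    return BPRegressor(config or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def make_training_arrays(
    frames: Sequence[FramePair],
    labels: Sequence[BPLabel],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack valid labeled frames into (X, y, record_ids), dropping invalid labels."""
    if len(frames) != len(labels):
        raise DataError(f"{len(frames)} frames but {len(labels)} labels")
    X, y, rid = [], [], []
    for f, lab in zip(frames, labels):
        if lab.valid:
            X.append(f.ecg)
            y.append((lab.sbp, lab.dbp))
            rid.append(f.source_record)
    if not X:
        raise DataError("no valid labeled frames")
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float), rid


def _split_indices(rng: np.random.Generator, n: int, record_ids: list[str],
                   cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    if cfg.split_mode == "record":
        recs = sorted(set(record_ids))
        perm = rng.permutation(len(recs))
        n_train = max(1, int(round(cfg.split_fraction * len(recs))))
        if n_train == len(recs):
            n_train -= 1
        train_recs = {recs[i] for i in perm[:n_train]}
        idx = np.arange(n)
        mask = np.array([r in train_recs for r in record_ids])
        return idx[mask], idx[~mask]
    perm = rng.permutation(n)
    n_train = int(round(cfg.split_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return perm[:n_train], perm[n_train:]


def train(
    model: BPRegressor,
    frames: Sequence[FramePair],
    labels: Sequence[BPLabel],
    cfg: TrainConfig | None = None,
) -> tuple[BPRegressor, TrainingHistory]:
    """Fit the regressor on labeled frames; returns the best-epoch checkpoint.

    The valid frames are split ``split_fraction`` / remainder into train and
    validation sets; targets are z-scored with statistics of the training
    split only; MSE on the standardized targets is minimized with Adam.
    Early stopping monitors validation loss with the configured patience and
    the returned model carries the parameters of the best epoch.
    """
    cfg = cfg or TrainConfig()
    X, y, record_ids = make_training_arrays(frames, labels)
    rng = np.random.default_rng(cfg.seed)
    tr, va = _split_indices(rng, len(X), record_ids, cfg)
    if tr.size == 0 or va.size == 0:
        raise DataError("empty train or validation split")
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    if cfg.standardize_targets:
        model.target_mean = ytr.mean(axis=0)
        model.target_std = np.maximum(ytr.std(axis=0), 1e-8)
    else:
        model.target_mean = np.zeros(2)
        model.target_std = np.ones(2)
    ztr = (ytr - model.target_mean) / model.target_std
    zva = (yva - model.target_mean) / model.target_std

    opt = _nn.Adam(model.params, lr=cfg.learning_rate)
    history = TrainingHistory(train_indices=tr.tolist(), val_indices=va.tolist())
    best_val = np.inf
    best_params = None
    since_best = 0

    for _epoch in range(cfg.max_epochs):
        if cfg.warmup_epochs > 0 and _epoch < cfg.warmup_epochs:
            opt.lr = cfg.learning_rate * (_epoch + 1) / (cfg.warmup_epochs + 1)
        elif _epoch == cfg.warmup_epochs:
            opt.lr = cfg.learning_rate
        order = rng.permutation(len(Xtr))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            b = order[lo:lo + cfg.batch_size]
            out, caches = model.forward(Xtr[b], want_cache=True)
            err = out - ztr[b]
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(
                    "training loss became non-finite; lower the learning rate "
                    "or enable gradient clipping")
            losses.append(loss)
            grads = model.backward((2.0 * err / err.size).astype(np.float32), caches)
            opt.step(grads, clip_norm=cfg.grad_clip)
        val = float(np.mean((model.forward(Xva) - zva) ** 2))
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
            if (cfg.lr_decay < 1.0 and since_best % cfg.lr_patience == 0
                    and opt.lr > cfg.min_lr):
                opt.lr = max(cfg.min_lr, opt.lr * cfg.lr_decay)

    if cfg.restore_best and best_params is not None:
        model.params = best_params
    return model, history


def predict(model: BPRegressor, frames: Sequence[FramePair] | np.ndarray) -> np.ndarray:
    """Per-frame (SBP, DBP) estimates in mmHg, shape (N, 2).

    Accepts a list of frames or a pre-stacked (N, frame_len) array.  Frames
    must have been conditioned identically to the training data.
    """
    if isinstance(frames, np.ndarray):
        X = frames if frames.ndim == 2 else frames[None, :]
    else:
        X = np.asarray([f.ecg for f in frames], dtype=float)
        if X.ndim != 2:
            raise ShapeError("frames have inconsistent lengths")
    if X.shape[1] != model.config.frame_len:
        raise ShapeError(
            f"frames have {X.shape[1]} samples; model expects {model.config.frame_len}")
    return model.predict_mmhg(X)


# ---------------------------------------------------------------------------
# Persistence: directory with config.json + weights.npz
# ---------------------------------------------------------------------------

def _weights_digest(params: dict[str, np.ndarray], config_dict: dict) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(config_dict, sort_keys=True).encode())
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k]).tobytes())
    return h.hexdigest()


def save_model(model: BPRegressor, path: str | Path) -> Path:
    """Serialize weights, architecture config and target scaling to ``path``.

    ``config.json`` carries a digest over config + weights so corruption or
    tampering is detected at load time rather than surfacing as silently
    wrong predictions.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(model.config)
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": cfg_dict,
        "seed": model.seed,
        "target_mean": model.target_mean.tolist(),
        "target_std": model.target_std.tolist(),
        "digest": _weights_digest(model.params, cfg_dict),
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    np.savez(path / "weights.npz", **model.params)
    return path

def load_model(path: str | Path) -> BPRegressor:
    """Load a model saved by :func:`save_model`; validates shape consistency."""
    path = Path(path)
    cfg_file, w_file = path / "config.json", path / "weights.npz"
    if not cfg_file.exists() or not w_file.exists():
        raise ModelPersistenceError(f"{path} is not a model directory")
    try:
        meta = json.loads(cfg_file.read_text())
    except json.JSONDecodeError as exc:
        raise ModelPersistenceError(f"corrupt config.json: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ModelPersistenceError(
            f"unsupported model format {meta.get('format_version')!r}")
    try:
        config = ModelConfig(**meta["config"])
    except (TypeError, KeyError, ConfigError) as exc:
        raise ModelPersistenceError(f"bad model config: {exc}") from exc
    model = BPRegressor(config, seed=int(meta.get("seed", 0)))
    try:
        with np.load(w_file) as npz:
            weights = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ModelPersistenceError(f"corrupt weights file: {exc}") from exc
    for k, ref in model.params.items():
        if k not in weights:
            raise ModelPersistenceError(f"missing weight array {k!r}")
        if weights[k].shape != ref.shape:
            raise ModelPersistenceError(
                f"weight {k!r} has shape {weights[k].shape}, config implies {ref.shape}")
    model.params = {k: np.asarray(v, dtype=np.float32) for k, v in weights.items()}
    if meta.get("digest") != _weights_digest(model.params, meta["config"]):
        raise ModelPersistenceError(
            "model directory failed its integrity check (config or weights modified)")
    model.target_mean = np.asarray(meta["target_mean"], dtype=float)
    model.target_std = np.asarray(meta["target_std"], dtype=float)
    return model
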