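"""Estimator evaluation against reference blood pressure.

Implements the device-validation style summaries used for cuffless BP
monitors: Pearson correlation between estimates and references, signed mean
error (ME) and error SD checked against AAMI-type thresholds
(|ME| <= 5 mmHg and SD <= 8 mmHg by default; thresholds are configuration,
not constants), BHS-type letter grades from the cumulative percentages of
absolute errors within 5/10/15 mmHg, and Bland-Altman bias / 95% limits of
agreement.  Thresholds are inclusive (<=) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import AlignmentError, DataError, UndefinedCorrelationError
from .labeling import BPLabel
from .model import BPRegressor, predict
from .preprocess import FramePair

#: default AAMI-style thresholds: (|mean error| mmHg, error SD mmHg)
AAMI_THRESHOLDS = (5.0, 8.0)
#: default BHS-style absolute-error bands, mmHg
BHS_BANDS = (5.0, 10.0, 15.0)
#: default BHS-style cumulative-percentage cutoffs per letter grade
BHS_GRADE_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


def _paired(est, ref, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise AlignmentError(f"estimate/reference length mismatch: {est.shape} vs {ref.shape}")
    if est.size < min_n:
        raise DataError(f"need at least {min_n} pairs, got {est.size}")
    return est, ref


def pearson_r(est: Sequence[float], ref: Sequence[float]) -> float:
    """Product-moment correlation between estimates and references."""
    est, ref = _paired(est, ref, min_n=3)
    if np.std(est) == 0 or np.std(ref) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(est, ref).statistic)


def error_stats(est: Sequence[float], ref: Sequence[float]) -> tuple[float, float, float]:
    """(mean error, sample SD of errors, mean absolute error), all in mmHg."""
    est, ref = _paired(est, ref)
    err = est - ref
    return float(err.mean()), float(err.std(ddof=1)), float(np.abs(err).mean())


def aami_check(me: float, sd: float,
               thresholds: tuple[float, float] = AAMI_THRESHOLDS) -> bool:
    """Pass iff |ME| <= thresholds[0] and SD <= thresholds[1] (inclusive)."""
    return bool(abs(me) <= thresholds[0] and sd <= thresholds[1])


def bhs_grade(
    errors: Sequence[float],
    bands: tuple[float, float, float] = BHS_BANDS,
    grade_table: dict[str, tuple[float, float, float]] | None = None,
) -> tuple[tuple[float, float, float], str]:
    """Cumulative percentages of |error| within the bands, and a letter grade.

    The grade is the best letter whose three cutoffs are all met; anything
    below the last row is "D".
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise DataError("empty error list")
    grade_table = grade_table or BHS_GRADE_TABLE
    pct = tuple(float(100.0 * np.mean(np.abs(errors) <= b)) for b in bands)
    for letter, cutoffs in grade_table.items():
        if all(p >= c for p, c in zip(pct, cutoffs)):
            return pct, letter
    return pct, "D"


def bland_altman(est: Sequence[float], ref: Sequence[float]) -> tuple[float, float, float]:
    """(bias, lower, upper): mean difference and 95% limits of agreement."""
    est, ref = _paired(est, ref)
    d = est - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class ChannelReport:
    """Agreement summary for one pressure channel (SBP or DBP)."""

    pearson_r: float | None
    me: float
    sd: float
    mae: float
    aami_pass: bool
    bhs_percentages: tuple[float, float, float]
    bhs_grade: str
    bland_altman: tuple[float, float, float]
    degenerate: bool = False  # zero-variance estimator; correlation undefined


@dataclass
class EvalReport:
    """Paired-estimate evaluation of a BP estimator."""

    n: int
    sbp: ChannelReport
    dbp: ChannelReport
    estimates: np.ndarray = field(repr=False, default=None)
    references: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {"n": self.n, "sbp": asdict(self.sbp), "dbp": asdict(self.dbp)}
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _channel_report(est: np.ndarray, ref: np.ndarray,
                    aami_thresholds=AAMI_THRESHOLDS) -> ChannelReport:
    me, sd, mae = error_stats(est, ref)
    degenerate = bool(np.std(est) == 0 or np.std(ref) == 0)
    r = None if degenerate else pearson_r(est, ref)
    pct, grade = bhs_grade(est - ref)
    return ChannelReport(
        pearson_r=r, me=me, sd=sd, mae=mae,
        aami_pass=aami_check(me, sd, aami_thresholds),
        bhs_percentages=pct, bhs_grade=grade,
        bland_altman=bland_altman(est, ref),
        degenerate=degenerate,
    )


def evaluate_pairs(est: np.ndarray, ref: np.ndarray,
                   aami_thresholds=AAMI_THRESHOLDS) -> EvalReport:
    """Build an :class:`EvalReport` from (N, 2) [SBP, DBP] estimate/reference arrays."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 2 or est.shape[1] != 2:
        raise AlignmentError(f"expected matching (N, 2) arrays, got {est.shape} vs {ref.shape}")
    if est.shape[0] < 2:
        raise DataError("need at least 2 estimate/reference pairs")
    return EvalReport(
        n=est.shape[0],
        sbp=_channel_report(est[:, 0], ref[:, 0], aami_thresholds),
        dbp=_channel_report(est[:, 1], ref[:, 1], aami_thresholds),
        estimates=est, references=ref,
    )


def evaluate_model(
    model: BPRegressor,
    frames: Sequence[FramePair],
    labels: Sequence[BPLabel],
    aami_thresholds: tuple[float, float] = AAMI_THRESHOLDS,
) -> EvalReport:
    """Predict on labeled frames and summarize agreement per channel.

    Frames with invalid labels are excluded; at least two valid frames are
    required.
    """
    pairs = [(f, lab) for f, lab in zip(frames, labels) if lab.valid]
    if len(pairs) < 2:
        raise DataError("need at least 2 validly labeled frames to evaluate")
    est = predict(model, [f for f, _ in pairs])
    ref = np.asarray([(lab.sbp, lab.dbp) for _, lab in pairs])
    return evaluate_pairs(est, ref, aami_thresholds)


def plot_report(report: EvalReport, out_dir: str | Path) -> list[Path]:
    """Scatter (estimate vs reference) and Bland-Altman plots per channel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    names = ["sbp", "dbp"]
    for j, name in enumerate(names):
        ch = getattr(report, name)
        est, ref = report.estimates[:, j], report.references[:, j]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(ref, est, s=8, alpha=0.6)
        lims = [min(ref.min(), est.min()), max(ref.max(), est.max())]
        ax1.plot(lims, lims, "k--", lw=1)
        r_txt = f"r = {ch.pearson_r:.3f}" if ch.pearson_r is not None else "r undefined"
        ax1.set(xlabel=f"reference {name.upper()} (mmHg)",
                ylabel=f"estimated {name.upper()} (mmHg)", title=r_txt)
        d = est - ref
        m = (est + ref) / 2
        bias, lo, hi = ch.bland_altman
        ax2.scatter(m, d, s=8, alpha=0.6)
        for yv, style in ((bias, "-"), (lo, "--"), (hi, "--")):
            ax2.axhline(yv, color="r", ls=style, lw=1)
        ax2.set(xlabel="mean of methods (mmHg)", ylabel="difference (mmHg)",
                title=f"bias {bias:.2f}, LoA [{lo:.2f}, {hi:.2f}]")
        fig.tight_layout()
        p = out_dir / f"{name}_agreement.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
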