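# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecg2bp`, and what the synthetic experiments do and do not show.

## Problem setting

Cuffless, continuous blood-pressure monitoring replaces the inflating cuff
with an estimate computed from a continuously measurable signal — here a
single ECG channel.  ECG carries BP-relevant information indirectly: beat
timing (heart rate and its variability) and beat morphology co-vary with
arterial pressure through autonomic regulation.  The estimator is trained
against reference pressures read from an invasive arterial line (ABP), whose
per-cycle maxima and minima define systolic and diastolic pressure.

## Synthetic data generator

The generator stands in for ICU-monitor style paired recordings and is the
ground-truth oracle for every pipeline stage.

**ECG.**  Each beat contributes five Gaussian waves (P, Q, R, S, T) with
fixed amplitudes (0.12, −0.15, 1.0, −0.25, 0.3 mV) and nominal offsets
(−0.20, −0.035, 0, 0.035, 0.25 s relative to the R peak).  Offsets and
widths scale with √RR of the current beat — the classic rate-adaptation of
the QT interval — so instantaneous rate is encoded in local morphology, as
in real ECG, not only in R-to-R distances.  Beat times are drawn with mean
rate `hr_bpm` and beat-to-beat SD `hr_sd` (default 75 ± 2 bpm).  Nuisance
terms: white noise (default SD 0.05 mV ≈ 5% of the R amplitude), a
power-line sinusoid (60 Hz, 0.02 mV) and sinusoidal baseline wander (0.2 Hz,
0.1 mV).

**ABP.**  Per beat, systolic pressure follows the coupling
`SBP_k = a + b·HR_k + ε_k` with defaults a = 90 mmHg, b = 0.5 mmHg/bpm and
ε ~ N(0, 2 mmHg); diastolic pressure is SBP minus a pulse pressure of
40 mmHg with independent N(0, 2 mmHg) noise; a slow sinusoidal drift
(amplitude 2 mmHg, one cycle per record) models within-record BP variation
the ECG cannot explain.  Each cycle is rendered as a raised-cosine systolic
upstroke and an exponential diastolic decay, constructed in the sample
domain so the waveform attains exactly SBP at the peak sample and exactly
DBP at the onset sample.  The ABP upstroke lags the R peak by 0.1 s (a
pulse-arrival-time stand-in) and peaks 30% into the cycle.

**Datasets.**  Between-record variation emulates between-patient variation:
the record's mean rate is jittered by N(0, 10 bpm) (clipped to 45–140 bpm)
and its pulse pressure by N(0, 3 mmHg).  All record seeds derive from one
master seed, so a dataset is bit-reproducible.

With these defaults, pooled frame SBP has SD ≈ 4.5 mmHg, of which
≈ 3.8 mmHg is heart-rate-driven (recoverable from ECG) and the rest (ε,
drift) is irreducible noise — an estimator recovering all rate information
would reach r ≈ 0.84 against frame labels.

**What the simulator does not emulate:** arrhythmia and ectopy, respiratory
modulation, motion artifacts, electrode changes, the diversity of real
pressure-wave morphology (dicrotic notch, reflections), or any BP dynamics
uncoupled from heart rate beyond a single slow drift term.  Passing the
synthetic recovery experiments therefore demonstrates the *pipeline's*
correctness and the network's capacity to extract rhythm-coded BP
information — not clinical accuracy on real patients.

## Signal conditioning

* **Low-pass:** 4th-order Butterworth, 50 Hz cut-off, applied
  forward–backward (`sosfiltfilt`): zero phase, so fiducial points shift by
  ≤ 1 sample; the squared magnitude response still attenuates a 58 Hz tone
  to < 1% at 125 Hz sampling.  Requires fs > 2·cutoff.
* **Baseline removal:** multilevel DWT (Daubechies-4); the decomposition
  depth is the smallest L with fs/2^(L+1) ≤ 0.5 Hz (L = 7 at 125 Hz), the
  approximation coefficients are zeroed, and the signal is reconstructed.
  This removes a 0.2 Hz wander to < 6% residual RMS while keeping a clean
  ECG correlated > 0.998 with its input.  A deeper decomposition (L = 8)
  narrows the approximation band to 0.24 Hz and leaves half the 0.2 Hz
  wander in place, which is why the depth rule targets the band edge rather
  than a fixed level.
* **Order:** low-pass first, then baseline removal; exposed in
  `PreprocessConfig`.  ABP is left unfiltered by default — its extrema are
  the labels and must not be attenuated.
* **Segmentation:** non-overlapping 128-sample frames; remainders are
  discarded (no padding), so frame concatenation is a partition of the
  conditioned signal's prefix.

## Label extraction

Systolic peaks / diastolic troughs are local extrema separated by a 0.3 s
refractory distance that clear an amplitude dead-band of ±5% of the frame's
dynamic range around its midrange value; peak and trough series are forced
to alternate (keeping the more extreme of same-kind neighbours).  Amplitude
gating was chosen over scipy peak prominence deliberately: an extremum a few
samples inside a frame boundary has a truncated flank, and its measured
prominence collapses even though the pressure value is exact — prominence
gating silently drops such beats and biases frame labels.  A frame's label
is the mean of its peak/trough amplitudes; frames with no usable extremum,
SBP ≤ DBP, SBP > 250 or DBP < 20 mmHg are flagged invalid and excluded from
training (bounds configurable).  At 125 Hz a 128-sample frame spans ~1.02 s
and contains one or two cycles.

## QRS detection and rhythm

The R-peak detector is the classic energy-transform chain: 5–15 Hz
band-pass, derivative, squaring, 150 ms moving-window integration, an
adaptive signal/noise threshold (running estimates updated with weight
0.125) with a 0.25 s refractory period, and refinement of each detection to
the local ECG maximum within ±100 ms.  On the standard noisy fixture (60
bpm, broadband noise at 10% of the R amplitude) it scores sensitivity and
positive predictivity ≥ 0.95 at 50 ms tolerance.  RR intervals and
instantaneous heart rate (60/RR) follow directly from the annotation.

## Network and training

Architecture (input: one 128-sample conditioned, per-frame z-scored ECG
frame):

| stage | output shape |
|---|---|
| conv(32, k=7, same) → ReLU → maxpool(2) | 32 × 64 |
| conv(64) → ReLU → pool | 64 × 32 |
| conv(128) → ReLU → pool | 128 × 16 |
| conv(256) → ReLU → pool | 256 × 8 |
| global average pool | 256 |
| dense 128, ReLU (feature layer) | 128 |
| dense 32 → dense 16, ReLU | 16 |
| dense 2, linear | (SBP, DBP) |

Design notes:

* After the fourth pool the tensor is 256 channels × 8 steps; global average
  pooling followed by the 128-unit dense layer realizes the "128 learned
  features" block with the mildest assumption consistent with the filter
  counts (a flatten would give 2,048 features).
* Kernel width 7 makes the deepest layer's receptive field ~91 samples
  (≈ 0.73 s at 125 Hz) — wide enough to span a full RR interval.  With
  k = 5 the receptive field is ≈ 0.49 s, rate information cannot be
  composed below the global pool, and held-out recovery degrades
  measurably.
* Pool size 2 is the only choice allowing four pools on length-128 input.

Training: MSE on z-scored targets (z-scoring estimated on the training split
only; a raw-mmHg MSE makes SBP dominate DBP), Adam with batch 32 and initial
learning rate 0.01, 80/20 frame-level random split (a record-level split
mode is provided and preferable when records proxy subjects, since
frame-level splits leak record identity), early stopping with patience 20
and restoration of the best-validation checkpoint.  Three stabilizers
protect the aggressive 0.01 rate: a 3-epoch linear warmup (without it the
ReLU network occasionally collapses to a constant predictor), global
gradient-norm clipping at 1.0, and halving of the rate on 5-epoch validation
plateaus.  All computation is float32 numpy (im2col convolutions with exact
analytic gradients, verified against finite differences); training is
deterministic for a fixed seed and takes ~1–3 s per epoch on one CPU at
2,500 frames.

`restore_best=False` returns the final-epoch parameters instead of the
best-validation checkpoint; the memorization test uses it, since capacity is
a property of the fitted network, not of the early-stopping rule.

## Evaluation

Per channel: Pearson r (an explicit error is raised on zero-variance input
rather than returning a silent 0; a constant estimator is flagged
`degenerate`), signed mean error, sample SD (n−1) and MAE, an AAMI-style
pass flag (|ME| ≤ 5 mmHg and SD ≤ 8 mmHg, inclusive boundaries,
configurable), BHS-style cumulative percentages of |error| within
5/10/15 mmHg graded A = (60, 85, 95), B = (50, 75, 90), C = (40, 65, 85),
else D (best letter whose three cutoffs are all met), and Bland–Altman bias
with 1.96·SD limits of agreement.

## Problem sizes and reproducibility

The canonical recovery experiment (`ecg2bp.experiments.parameter_recovery`)
uses exactly 2,500 validly labeled frames (~45 one-minute records), split
2,000 train / 500 held-out; the QRS fixture is one 10 s record at 60 bpm.
Every random choice — simulation, record jitter, splits, weight
initialization, batch order — derives from one seed, and identical
config + seed reproduce every artifact, including the evaluation report,
byte for byte on a given platform.

## Known limitations

* The synthetic coupling is linear in heart rate; the network is not tested
  against nonlinear or lagged BP dynamics.
* Calibration transfer (training on one population, testing on another) is
  out of scope; the record-level split is the closest provided proxy.
* DBP recovery is weaker than SBP by construction (independent
  pulse-pressure noise enters DBP only), typically r ≈ 0.65–0.8 on the
  default conditions.
* WFDB support covers the minimal header + format-16 subset, not the full
  standard (no annotation files, multi-segment records, or other signal
  formats).
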