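# ecg2bp — cuffless blood-pressure estimation from single-channel ECG

`ecg2bp` implements a continuous, cuffless blood-pressure (BP) estimation
pipeline for physiological-signal researchers: a small one-dimensional
convolutional network regresses each ~1-second window of a single ECG channel
onto that window's systolic and diastolic pressure (SBP, DBP) in mmHg, with
the training targets read off a simultaneously recorded arterial-blood-
pressure (ABP) waveform.  The package also covers the surrounding workflow —
waveform I/O, ECG conditioning, QRS / RR-interval / heart-rate analysis, and
device-validation style reporting — and ships a coupled ECG/ABP simulator so
the whole pipeline is testable end to end without access to any clinical
waveform database.

## Method

Given paired ECG and ABP signals sampled at a common rate (125 Hz by
default):

1. **Conditioning** — the ECG is low-pass filtered at 50 Hz (4th-order
   Butterworth, applied forward–backward so R-peak timing is preserved) and
   baseline drift is removed by a multilevel Daubechies-4 wavelet
   decomposition with the sub-0.5 Hz approximation band zeroed.
2. **Segmentation** — both channels are tiled by a non-overlapping sliding
   window into frames of 128 samples; the trailing remainder is discarded.
3. **Labeling** — systolic peaks and diastolic troughs are extracted from
   each ABP frame; the frame label is (mean peak amplitude, mean trough
   amplitude) = (SBP, DBP).
4. **Regression** — a 1D-CNN with four conv+max-pool stages (32, 64, 128,
   256 filters), a 128-unit feature layer and fully connected layers of 32
   and 16 nodes maps the ECG frame to a linear 2-output (SBP, DBP) head.
   Training minimizes MSE on z-scored targets with Adam (batch 32, initial
   learning rate 0.01), 80%/20% train/evaluation split, early stopping on
   validation loss.
5. **Evaluation** — Pearson r against reference pressures, mean error (ME)
   and error SD against AAMI-style thresholds (|ME| ≤ 5, SD ≤ 8 mmHg),
   BHS-style letter grades from the cumulative percentages of absolute
   errors within 5/10/15 mmHg, and Bland–Altman agreement limits.

The simulator generates beat-synchronous ECG (Gaussian P/Q/R/S/T waves with
rate-adaptive morphology) and ABP (per-cycle maximum = SBP, minimum = DBP)
sharing the same beat times, linked by an explicit coupling
`SBP = a + b·HR + ε` (defaults a = 90 mmHg, b = 0.5 mmHg/bpm,
ε ~ N(0, 2 mmHg)), plus broadband noise, power-line interference and
baseline wander.  Ground-truth beat times and per-beat pressures make it an
exact oracle for every downstream stage.  See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```python
from ecg2bp import SyntheticConfig, simulate_dataset
from ecg2bp.preprocess import preprocess_record
from ecg2bp.labeling import label_frames
from ecg2bp.model import ModelConfig, TrainConfig, build_model, train
from ecg2bp.evaluate import evaluate_model

records = simulate_dataset(SyntheticConfig(duration_s=60.0, seed=15), n_records=8)
frames, labels = [], []
for rec, _ in records:
    fr = preprocess_record(rec)
    frames += fr
    labels += label_frames(fr, rec.fs)

model = build_model(ModelConfig(), seed=15)
model, history = train(model, frames, labels,
                       TrainConfig(max_epochs=30, patience=10, seed=15))
valid = [(f, l) for f, l in zip(frames, labels) if l.valid]
held_out = [valid[i] for i in history.val_indices]
report = evaluate_model(model, [f for f, _ in held_out], [l for _, l in held_out])
print(report.sbp)
```

Running this (it is `examples/train_and_evaluate.py`) prints:

```
trained 18 epochs; best epoch 7 (val MSE 0.351 on z-scored targets)
SBP: r=0.835  MAE=2.36 mmHg  ME=+0.83  SD=2.79  AAMI=pass  BHS=A
DBP: r=0.725  MAE=3.58 mmHg  ME=-0.53  SD=4.26  AAMI=pass  BHS=A
```

i.e. on held-out frames the ECG-only network recovers SBP with 2.4 mmHg mean
absolute error and correlation 0.84 against the ABP-derived reference — most
of the variance the simulator's HR→BP coupling makes recoverable — and the
error distribution satisfies the AAMI-style mean-error/SD thresholds and
grades A on the BHS-style cumulative-error scale.

The other scripts in `examples/` demonstrate rhythm analysis
(`simulate_and_inspect_rhythm.py`), conditioning and labeling
(`condition_and_label_frames.py`), and the one-config full pipeline
(`full_pipeline_run.py`).  The same stages are available from a shell via
the `ecg2bp` command (`simulate`, `preprocess`, `label`, `qrs`, `train`,
`predict`, `evaluate`, `run`).

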