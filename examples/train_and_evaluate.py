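"""Train the 1D-CNN BP estimator on synthetic frames and grade the result.

A scaled-down version of the full study (8 records, ~460 frames, short
training) so it runs in well under a minute; see scripts/acceptance.py for
the full 2,000-frame experiment.
"""

from ecg2bp import SyntheticConfig, simulate_dataset
from ecg2bp.evaluate import evaluate_model
from ecg2bp.labeling import label_frames
from ecg2bp.model import ModelConfig, TrainConfig, build_model, train
from ecg2bp.preprocess import preprocess_record

records = simulate_dataset(SyntheticConfig(duration_s=60.0, seed=15), n_records=8)
frames, labels = [], []
for rec, _ in records:
    fr = preprocess_record(rec)
    frames += fr
    labels += label_frames(fr, rec.fs)

model = build_model(ModelConfig(), seed=15)
model, history = train(model, frames, labels,
                       TrainConfig(max_epochs=30, patience=10, seed=15))
print(f"trained {history.n_epochs} epochs; best epoch {history.best_epoch} "
      f"(val MSE {history.val_loss[history.best_epoch]:.3f} on z-scored targets)")

valid = [(f, l) for f, l in zip(frames, labels) if l.valid]
held_out = [valid[i] for i in history.val_indices]
report = evaluate_model(model, [f for f, _ in held_out], [l for _, l in held_out])
for name in ("sbp", "dbp"):
    ch = getattr(report, name)
    print(f"{name.upper()}: r={ch.pearson_r:.3f}  MAE={ch.mae:.2f} mmHg  "
          f"ME={ch.me:+.2f}  SD={ch.sd:.2f}  AAMI={'pass' if ch.aami_pass else 'fail'}  "
          f"BHS={ch.bhs_grade}")
# r is the correlation between estimated and reference pressures on held-out
# frames; AAMI requires |ME| <= 5 and SD <= 8 mmHg; BHS letters come from the
# cumulative percentages of absolute errors within 5/10/15 mmHg.
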