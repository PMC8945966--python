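"""Run the whole pipeline from one JSON-style config (simulate -> report).

Equivalent to `ecg2bp run --config cfg.json`; every artifact (frozen config,
frames, model, history, report, plots, log) lands in one run directory, and
rerunning with the same config + seed reproduces the report byte for byte.
"""

import json

from ecg2bp.pipeline import run_pipeline, validate_config_dict

cfg = validate_config_dict({
    "seed": 33,
    "synth": {"n_records": 6, "duration_s": 45},
    "train": {"max_epochs": 20, "patience": 8},
    "evaluate": {"plots": True},
})
run_dir = run_pipeline(cfg, "scratch/example-run")
report = json.loads((run_dir / "report.json").read_text())

print(f"artifacts in {run_dir}:")
for p in sorted(run_dir.iterdir()):
    print("  ", p.name)
print(f"held-out frames: {report['n']}")
print(f"SBP r={report['sbp']['pearson_r']:.3f} MAE={report['sbp']['mae']:.2f} mmHg, "
      f"BHS {report['sbp']['bhs_grade']}")
print(f"DBP r={report['dbp']['pearson_r']:.3f} MAE={report['dbp']['mae']:.2f} mmHg, "
      f"BHS {report['dbp']['bhs_grade']}")
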