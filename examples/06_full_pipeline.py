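"""The configuration-driven pipeline end to end, at desk scale.

Equivalent to `seedspec run-all` with a YAML config: simulate ->
pretreat -> select -> cross-validated training over a (d, D) grid ->
aggregate report.  A reduced grid keeps this example to ~a minute.
"""

from seedspec.pipeline import PipelineConfig, report_summary, run_pipeline

cfg = PipelineConfig.model_validate({
    "simulate": {"n_classes": 4, "n_per_class": 24, "n_bands": 80},
    "spa": {"k_max": 8},
    "cars": {"n_runs": 20},
    "grid": {"depth_factors": [0.75, 1.0], "map_dims": [192, 768]},
    "train": {"epochs": 500, "batch_size": 16, "folds": 3},
    "output_dir": "runs/example",
    "seed": 0,
})
run_dir = run_pipeline(cfg)
print(f"artifacts in {run_dir}/ (selection JSONs, per-fold reports, plots)")
df = report_summary(run_dir)
cols = ["model", "fold", "train_pct", "test_pct", "params", "macs", "test_pct_mean"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# test_pct_mean is the 3-fold CV mean per model; params/macs grow with d and D
# while accuracy need not (wider mappings add redundancy, not signal).
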