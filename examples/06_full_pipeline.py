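"""The end-to-end pipeline: simulate -> PCA -> select -> classify -> compare.

Runs every feature family (three component-loading families and three
single-task families) with identical folds and prints the comparison.
A coarse SVM grid keeps the example quick; drop `grid_resolution` for the
default 20 x 20 search.
"""

from taskpca import PipelineConfig, run_all

manifest = run_all(PipelineConfig(seed=42, grid_resolution=8), out_dir="pipeline_out")

print(f"{'family':8s} {'lambda':>8s} {'#feat':>5s} {'acc':>5s} {'rec':>5s} "
      f"{'prec':>5s} {'spec':>5s} {'F2':>5s}")
for family in ("PC1", "PC2", "PC3", "picture", "sound", "Stroop"):
    lam = manifest.selected_lambda.get(family)
    n_sel = len(manifest.selected_features.get(family, []))
    m = manifest.metrics.get(family)
    if m is None:
        print(f"{family:8s} {lam:8.4f} {n_sel:5d}   (no features selected)")
        continue
    d = m["display"]
    print(f"{family:8s} {lam:8.4f} {n_sel:5d} {d['accuracy']:5.2f} "
          f"{d['recall']:5.2f} {d['precision']:5.2f} {d['specificity']:5.2f} "
          f"{d['F2']:5.2f}")
print("\nreports written to pipeline_out/ (manifest.json, metrics.json, "
      "features_*.tsv, deviance_*.json)")
# With the effect planted in component-2 loadings, the PC2 family matches or
# beats every single-task family; a family whose minimum-deviance model is
# empty (often PC1) gets no classifier, mirroring the analysis it emulates.
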