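# mccims

Analysis pipeline for multi-capillary-column ion-mobility-spectrometry
(MCC-IMS) breath measurements: from raw retention-time × inverse-reduced-ion-
mobility intensity heatmaps to an interpretable classification model.

The pipeline covers:

* **Preprocessing** — RIP-anchored intensity normalization to [0, 1],
  per-spectrum 25%-quantile baseline correction, noise estimation from the
  low-IRM region (< 0.4 Vs/cm²) and subtraction, Daubechies-8 wavelet
  denoising, Gaussian / median / Savitzky–Golay smoothing.
* **Peak detection** — tophat filtering, the JIBB rising-signal heuristic,
  a falling-water-level watershed, rectangle extraction from VisualNow-style
  layer annotations, and an optional subprocess hook for an external PEAX
  binary.
* **Peak alignment** — deterministic probe clustering on a fixed grid whose
  RT row heights follow the recurrence `H(0)=0, H(1)=3, H(q)=(2+srt)·H(q−1)`
  (clipped at 2000 s; constant IRM column width `w`, domain 1.6 Vs/cm²), or
  DBSCAN on normalized peak positions with grid-based cluster labeling.
* **Feature engineering** — presence-based feature reduction (minimum
  intensity + per-class percentage threshold), two-sided Mann–Whitney U
  tests with Benjamini–Hochberg FDR, random-forest mean decrease in Gini
  impurity, top-n selection.
* **Modeling** — dynamic fold selection (`k = min(⌊n_min/5⌋, 10)`, CV
  omitted below 10 minority samples), stratified cross-validation with
  accuracy / F1 / sensitivity / specificity / ROC-AUC, best-method
  selection by mean ROC-AUC, final random forest plus an interpretable
  decision tree, and prediction on new raw measurements or feature
  matrices from a self-contained, text-only model bundle.
* **Synthetic data** — a generator for measurements with a reactant ion
  peak (with exponential tailing), class-conditional analyte peaks and
  noise, with exact ground truth for fully offline validation.

All on-disk artifacts are plain CSV/JSON (see `mccims/io_formats.py` for
the dialects).

## CLI

```bash
# generate a synthetic dataset with ground truth
mccims synth --preset minimal --seed 1 --out data/

# stratified train/validation split of a labels file
mccims split --labels data/labels.csv --train-ratio 0.8 --out split/

# fully automatic analysis (all detection methods, best by mean ROC-AUC)
mccims auto --input data/ --labels data/labels.csv --seed 1 --out results/

# step-wise analysis from an explicit JSON stage configuration
mccims custom --input data/ --labels data/labels.csv --config cfg.json --out results/

# analyze a precomputed feature matrix (skips preprocessing/detection)
mccims existing --feature-matrix fm.csv --labels labels.csv --out results/

# predict labels for new measurements with a trained bundle
mccims predict --bundle results/bundle --input newdata/ --out predictions/

# summarize a result directory
mccims report --results results/
```

Every run writes `resolved_config.json` next to its outputs; a result
directory is reproducible from that file and the seed. Outputs include
`scores.csv` (q-values, Gini importances, ranks, peak coordinates),
`report.json` + `roc_points.csv`, per-method feature matrices, and a
`bundle/` directory (parameters, training features, decision tree as DOT
and text) from which models are refit deterministically at load time.

Exit codes: 0 success, 1 internal error, 2 bad user input.

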