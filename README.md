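# mitoscreen

Quantification toolkit for tandem-tag (EGFP–mCherry) mitophagy reporter
imaging and siRNA-screen analysis:

- **`synthetic_data`** — generators for two-channel reporter scenes (yellow
  mitochondrial networks + red-only mitolysosome puncta, with channel-gain
  imbalance, background, blur and shot/read noise), morphology-phenotype
  image sets, screen plates with planted effect sizes, section/puncta object
  fields, and PPI testbeds. Every generator emits machine-readable ground
  truth, so the whole pipeline is testable offline.
- **`image_core`** — background correction, nuclei/cell/mitochondria
  segmentation, Manders colocalization.
- **`ratiometric`** — the core scoring: red-channel weight calibration on
  non-mitophagy controls, per-pixel green/(w·red) ratio maps, red-only
  structure detection at the 0.5 threshold, per-cell quantification, and
  object-integrated variants (per-object ratio calls, grid counting, puncta
  colocalization frequency).
- **`morphology`** — per-cell shape features and a random-forest
  fragmented-vs-tubular classifier with per-class holdout accuracy.
- **`screen`** — per-well summaries with cell-count QC, normalization to
  siNT controls (centered so controls sit at 0), Dunnett many-to-one testing
  (Monte Carlo max-|t|; exact t-test for k=1), and primary/deconvolution hit
  calling (≥2 of 3 oligos, concordant direction).
- **`ppi`** — MITAB-style interaction parsing into a simple undirected graph
  and compartment-percentage profiles of candidate interactors with a
  screen-wide baseline.

## CLI

```bash
mitoscreen simulate field --seed 1 --out out/field
mitoscreen simulate plate --config plate.json --seed 1 --out out/plate
mitoscreen simulate morphology --n-per-class 10 --classes tubular,fragmented --seed 1 --out out/morph
mitoscreen simulate ppi --n-genes 50 --n-edges 200 --seed 1 --out out/ppi

mitoscreen score --plate out/plate --layout out/plate/layout.csv --out out/scored
mitoscreen morph train --features features.csv --model model.joblib
mitoscreen morph apply --features features.csv --model model.joblib
mitoscreen screen --wells out/scored/wells.csv --tier primary --alpha 0.05 --out results.csv
mitoscreen ppi --network net.mitab --annotations ann.tsv --candidates cands.txt --out profile.csv
```

Fields are written as one 16-bit grayscale TIFF per channel; ground truth
as label TIFFs plus CSV tables; plate layouts as CSV.

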