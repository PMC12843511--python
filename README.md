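# orgfate

Organoid time-lapse morphometrics and early tissue-fate prediction.

Retinal organoids grown one-per-well in 96-well plates are strongly
heterogeneous: under identical conditions some develop retinal pigmented
epithelium (RPE) or a lens and some do not, and the sizes of those tissues
vary widely. `orgfate` implements the computational side of predicting such
tissue outcomes from brightfield time-lapse imaging *before* the tissues
become visible, for researchers who want to study or benchmark this kind of
pipeline without access to the raw imaging data: every stage runs on a
seeded synthetic data generator with known ground truth.

The pipeline, in the order it runs:

1. **`synthetic_acquisition`** — seeded synthetic plates with the real
   acquisition geometry (96 wells, images every 30 min over 72 h = 144
   loops, 5 z-slices 50 µm apart, middle slice sharpest), a latent fate cue
   present from the first frame, late visible RPE/lens structures,
   experiment-level batch effects, and endpoint stereo-like images.
2. **`segmentation`** — pluggable soft-mask segmenter (classical default:
   Yen threshold + fill + largest component) with the published QC rules:
   area-average resample to 512 px, linear upsample, binarisation at
   0.5 × max, rejection of multi-component masks and bounding boxes over
   360 px.
3. **`morphometrics`** — exactly 165 named shape/intensity/moment features
   per accepted frame, including the custom descriptors (blur = in-mask
   Laplacian variance, ROI contrast, modal value, integrated density,
   aspect ratio, roundness, circularity = 4πA/P², compactness, effective
   diameter = 2√(A/π), convexity, ...).
4. **`toi_quantification`** — pigment area via Yen ROI → 8-bit → in-ROI
   min–max rescale → Sauvola local threshold (radius 15, k 0.5, r 128,
   t = m(1 + k(s/r − 1))); lens areas as circles (πr²); 4-level size
   classes from tercile cutoffs (class 0 = absent), with reference cutoffs
   RPE 4,541.73 / 7,548.51 µm² and lens 16,324.85 / 29,083.23 µm²; a
   bin-centre-distance diagnostic.
5. **`heterogeneity`** — z-scale → 20 principal components; mean pairwise
   inter-organoid distance per loop, winsorised (2.5/97.5 pct) consecutive
   -loop change, k = 30 neighbour Jaccard and same-organoid-neighbour
   diagnostics.
6. **`partitioning`** — leave-one-experiment-out folds with organoid-grouped
   90/10 train/validation splits, two-annotator consensus with a seeded
   coin flip on disagreement, and the balanced 6-annotator × 6-timeframe
   expert-panel sampler.
7. **`prediction`** — feature classifiers (any fit/predict_proba estimator;
   scalers fitted on training rows only), mask-centred 360→224 px crops, a
   small numpy-implemented CNN (class-weighted cross-entropy, gradient
   clipping at 1.0, LR halved on plateau, best state by validation loss,
   shuffled-label baseline twins), temperature-scaling calibration,
   validation-F1-weighted ensembling, per-loop weighted-F1 curves,
   bin-distance-stratified F1, per-experiment time-normalised trapezoidal
   AUC + paired Wilcoxon (Pratt) + Holm–Bonferroni, and PCA-15/k-means-4
   morphology-cluster targets.
8. **`saliency`** — consensus metrics over stored attribution maps
   (z-scored inside the organoid mask): pairwise top-1/5/10 % Dice,
   cross-model Spearman rank consistency, top-10 % Shannon entropy and
   centre-of-mass drift, SLIC-superpixel region votes; HDF5 map store.

`orgfate.workflows` composes the stages into desk-scale studies.

## Worked example

Generate a small study, extract morphometrics through the segmentation QC,
and train an outcome predictor on one leave-one-experiment-out fold:

```python
import pandas as pd
from sklearn.linear_model import LogisticRegression

from orgfate.synthetic_acquisition import AcquisitionConfig, FateSpec, simulate_study
from orgfate.morphometrics import compute_morphometrics
from orgfate.partitioning import make_loeo_splits
from orgfate.prediction import train_feature_classifier, f1_over_time

cfg = AcquisitionConfig(n_experiments=3, wells_per_plate=12, duration_h=12,
                        interval_min=30, frame_px=96, seed=0)
wells = simulate_study(cfg, FateSpec(signal_strength=1.0))
print(f"{len(wells)} organoids, {cfg.n_loops} loops, "
      f"{sum(w.outcome.rpe_present for w in wells)} RPE-fated")

table = compute_morphometrics(wells)
print(f"morphometrics table: {table.shape[0]} rows x {table.shape[1] - 3} features")

labels = pd.Series({(w.experiment_id, w.well_id): int(w.outcome.rpe_present)
                    for w in wells})
split = make_loeo_splits(table[["experiment_id", "well_id"]].drop_duplicates(),
                         seed=0)[0]
run = train_feature_classifier(table, labels, split,
                               LogisticRegression(max_iter=2000))
curve = f1_over_time(run, subset="test")
print("test-set weighted F1 at loops 0-4:",
      [round(f, 2) for f in curve["f1"].head(5)])
```

Output:

```
36 organoids, 24 loops, 14 RPE-fated
morphometrics table: 847 rows x 165 features
test-set weighted F1 at loops 0-4: [0.91, 1.0, 0.82, 0.82, 0.82]
```

36 wells were simulated over 24 loops; a few frames were dropped by the QC
rules, leaving 847 accepted rows of 165 features. With a strong latent cue
(`signal_strength=1.0`) the classifier predicts which organoids will form
RPE from the very first frames — loops 0–4 lie well before the pigment is
rendered — at weighted F1 around 0.8–1.0 on the held-out test experiment.
With `signal_strength=0.0` the same pipeline stays at chance, matching the
design that the cue is then absent.

A thin CLI mirrors the stages
(`orgfate simulate | segment | features | quantify | split | panel-sample |
heterogeneity | saliency-metrics`); see `orgfate --help`.

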