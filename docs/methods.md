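# Methods

This note documents the models, conventions, and numerical choices behind
`orgfate`, and what the synthetic-data generator does and does not emulate.

## The synthetic acquisition model

Real data of this kind are brightfield time-lapse stacks of single retinal
organoids, one per well of a 96-well plate, imaged every 30 min for 72 h
(144 loops) as five z-slices spaced 50 µm around the focal plane, with only
the middle slice used for analysis. The generator reproduces this geometry
exactly (all counts are configurable; the defaults are the real design) and
renders each frame on demand from a small set of per-well parameters, so a
full-size plate (69,120 images) costs nothing until frames are requested.

**Scene.** Each organoid is a star-convex blob: radius
R(t)·(1 + irregularity·t·Σₖ aₖ cos(kθ+φₖ)) with harmonics k = 2…5 drawn
per well, plus per-loop boundary jitter whose amplitude ramps with
normalised time t. R(t) grows linearly by 50 % over the series. Because
all wells start near-spherical and acquire their individual irregularity
over time, the population diverges morphologically with loop index — the
generator's analogue of the observed increase of inter-organoid distance —
and the per-loop jitter makes consecutive-frame change grow as well.
Intensities (8-bit): bright background ≈ 205, darker tissue ≈ 130 with a
radial dome, smooth per-frame texture, pixel noise before blur and a small
amount after. Defocus is a Gaussian PSF with σ = 0.5 + 1.1·|z − mid| px,
so the middle slice is always the sharpest; excluded loops render with an
extra 3 px of blur (the focus loss that would have triggered exclusion).

**Field of view.** `um_per_px` defaults to 512/frame_px, i.e. the scene is
always 512 µm across regardless of raster size; outcome areas in µm² are
therefore comparable between a 512-px "full" render and the 96-px desk
rasters used in tests. No microscope calibration is available for the real
system, so the absolute scale is a convention, exposed in the config.

**Fates.** Each well independently draws an RPE fate (probability 0.5) and
a lens fate (0.5). Visible structures appear only late: the pigment patch
(dark, anchored off-centre) from loop ≈ 44/72 of the window and the lens
disc (bright, near-central, opposite half-plane) from ≈ 35/72, each growing
to its final area by the last loop. Final areas are lognormal with
parameters chosen so the pooled tercile cutoffs land near the reference
values (RPE 4,541.73/7,548.51 µm²; lens 16,324.85/29,083.23 µm²); lens
areas are clipped to fit inside the organoid, which truncates only the
upper tail.

**The latent cue.** Before visibility, fated and non-fated organoids differ
only by a subtle oriented sinusoidal texture inside the mask, amplitude
25·`signal_strength` gray levels, present from loop 0. The two fates use
distinct orientations *and* spatial frequencies (RPE 0.18 cycles/px fine,
lens 0.05 coarse) so each is recoverable from second-order statistics
without being confounded by the other. At `signal_strength = 0` the cue is
absent and pre-visibility frames of fated and non-fated wells are drawn
from the same distribution — the exchangeability every negative-control
test relies on. The default 0.4 keeps the cue invisible to thresholding
but detectable; "strong signal" studies use 1.0.

**Stereo endpoint images.** RPE areas are measured on a stereo-like render
of the final state: bright background, gently shaded tissue, the pigment
patch stamped sharp and exactly black after the optics blur (dense pigment
saturates the sensor floor in stereo imaging), and a few 1–2 px dark
micro-debris specks in every organoid. The debris matters: the
quantification chain min–max rescales intensities inside the ROI, which
presumes genuinely dark content exists; on a debris-free, pigment-free
organoid the rescale would stretch pure noise and the local threshold
would flag a few percent of tissue. Real stereo images always contain dark
specks; the renderer makes that explicit.

**What the generator does not emulate.** Photorealistic organoid texture;
fluorescence; multi-organoid wells; drift or stage artefacts beyond a slow
centroid walk; any correlation between fate and early *shape* (the cue is
purely textural). Passing tests therefore show that the pipeline's
machinery is correct and that it recovers signals of the kind injected;
they do not show that real organoid fate signals are of that kind, nor
predict real-data F1 levels, which depend on the full dataset and
GPU-trained networks.

## Segmentation and QC

The working resolution is 512 px (area-average down, linear up — the
standard INTER_AREA/INTER_LINEAR pairing, here via scikit-image). The
default segmenter is classical — Gaussian smoothing (σ scaled to the
working grid), Yen's threshold with foreground as the minority side, hole
filling, largest component — and is accurate for single round objects on a
homogeneous background; any callable producing a soft [0, 1] map at the
working resolution can replace it (e.g. a trained network). Binarisation
is at 0.5 × max of the soft map. QC: more than one connected component, or
a bounding-box side above 360 px, rejects the frame. The 360-px rule is
evaluated at the 512-px working resolution (the choice is stated in the
code; when a smaller working grid is configured the limit scales
proportionally). Rejection is a result state, not an error, and rejected
frames simply produce no morphometrics row. Bright-lens frames can defeat
the Yen default (the threshold may isolate the lens instead of the
organoid); such frames fail QC honestly rather than yielding wrong masks.

## The 165-feature registry

The count is contractual; the exact composition is pinned in
`morphometrics.py` (22 geometry + 12 intensity + 7 custom shape + 9 custom
intensity + 115 moment features: binary raw/central moments on the full
5×5 order grid with normalised moments to order 4 and the 7 Hu invariants,
and intensity-weighted counterparts on the 4×4 grid with order-3
normalised moments and weighted Hu invariants). Standard descriptors come
from scikit-image regionprops on the mask's local window; moments follow
the regionprops (row, col) convention.

Deterministic conventions: Laplacian = 4-neighbour kernel with mirror
boundary; modal-value ties break to the smallest intensity;
skewness/kurtosis (population, excess) of a constant in-mask distribution
are defined as 0; circularity and form factor share 4πA/P² (both names are
in common use and both are kept as registry entries). Every custom feature
is checked against an independent pixel-loop implementation to 1e-9.
Features default to the middle z-slice; sum- and maximum-intensity
z-projections are supported as alternative inputs.

## Tissue-outcome quantification

The Sauvola primitive returns the *bright* side of
t = m(1 + k(s/r − 1)) (foreground iff pixel > t), computed over a square
mirror-padded window of side 2·radius + 1 via uniform filters, which makes
it exactly equivalent to the brute-force definition. Pigment is the
complement inside the ROI — darker than the local Sauvola threshold —
which is the method's standard dark-foreground usage; a literal inversion
of the image before thresholding would invalidate Sauvola's
bright-background assumption and flood the mask, so the complement
convention is used and stated here. The full RPE chain: Yen ROI
(threshold-inclusive dark side, largest component, holes filled) → 8-bit
(linear min–max, round half-to-even) → in-ROI min–max rescale to [0, 255]
→ Sauvola (radius 15, k 0.5, r 128) → dark-pixel count × µm²/px². A flat
ROI yields area 0 with a warning. Known limitation: uniform dark patches
much larger than the window are hollowed by any local threshold; the
chain is accurate when pigment is near-saturated dark, as it is in stereo
images and in the renderer.

Lens areas are circles, πr², from ground truth, a two-point diameter
annotation, or a circle fit to the bright disc (threshold midway between
the 25th-percentile in-mask intensity and the maximum — robust even when
the lens covers most of the mask).

Size classes: 0 = absent; 1/2/3 by tercile cutoffs of pooled positive
areas with left-closed bins (area ≤ q33 → class 1, matching the "below"
phrasing of the class definitions; the boundary tie-break is stated here
because it is otherwise underdetermined). The cutoffs are computed at
exact tercile ranks (100/3, 200/3): rounding to the 33rd/66th integer
percentiles would systematically inflate the top class and break the
equal-group property the binning exists for. The bin-centre distance is
|area − centre|/half-width within bins bounded by (min, q33], (q33, q66],
(q66, max], so 0 at the centre and 1 at either edge.

## Heterogeneity statistics

Features are z-scaled and projected to 20 principal components (fitted per
analysis population; when a subset is analysed, scaling is fitted before
subsetting to preserve the numerical space; constant features are dropped
with a warning using a relative tolerance). All distances are Euclidean
in PC space. The consecutive-loop change series is winsorised at the
2.5th/97.5th percentiles of the pooled series before aggregation; SEM is
sd/√n over contributing organoids per loop; gaps in a trajectory are
skipped, never bridged. Neighbour diagnostics use k = 30 by default, the
query point excluded, distance ties broken by row index for determinism.

## Partitioning and sampling

Leave-one-experiment-out: one fold per experiment; the remaining organoids
split 90/10 at the organoid level (floor, minimum one validation organoid)
so no organoid's frames cross partitions — leakage is impossible by
construction and asserted. Consensus ground truth: agreement → high
confidence; disagreement → a seeded fair coin picks the annotator. The
expert-panel sampler bins loops into six equal timeframes (24 loops of
12 h each at the full design), assigns one image per available
well-timeframe to each of six annotators (without replacement when ≥ 6
unique images, with replacement otherwise), skips empty well-timeframes
for all annotators so loads stay equal, and draws from one RNG stream per
(experiment, well, timeframe) so adding wells never perturbs existing
assignments.

## Prediction, calibration, evaluation

Tabular path: z-score then min–max to [0, 1], statistics fitted on
training rows only and reused for validation/test; any estimator with
fit/predict_proba plugs in; a halving-style random hyperparameter search
(factor 3, 5-fold CV) is available for tuning. Image path: mask-centred
360-px crop (padded with the background median at frame edges) resampled
to 224 px, scaled to [0, 1], organoid pixels standardised in place with
background left untouched. The default trainable image model is a small
convolutional network implemented in numpy (input block-mean-pooled to
28 px, two 3×3 convolution blocks, global average pooling, softmax head;
Adam, class weights w_c = n/(K·n_c), global gradient-norm clipping at 1.0,
learning rate halved when the validation loss plateaus with patience 7 at
a 1e-4 relative threshold, best state restored by validation loss); larger
architectures plug in behind the same contract. Baseline twins train on
organoid-level label shuffles and are always *scored* against true labels.
The plateau scheduler and all model selection monitor the validation set
only; the test experiment is never touched before evaluation.

Temperature scaling fits a single T > 0 minimising validation
cross-entropy of softmax(logits/T) by bounded 1-D search on log T; being
monotone it never changes argmax predictions. Ensembles weight calibrated
probabilities by each member's best per-loop validation F1. Evaluation is
weighted-average F1 per loop; curves are compared across methods by
per-experiment trapezoidal AUC normalised by the time span (= the
time-averaged F1), paired Wilcoxon signed-rank tests with the Pratt
zero-difference policy (deterministic under ties), and Holm–Bonferroni
adjustment across method pairs; unpaired experiments are dropped with a
warning. Morphology-cluster targets: z-scale final-loop features, 15
principal components, seeded k-means with k = 4 and 10 restarts.

## Saliency consensus

Attribution maps are inputs (any backend, or the labelled synthetic
fixture generator); metrics never read outside the organoid mask. Each map
is z-scored inside the mask. Pairwise method agreement: Dice of the binary
top-1 %, 5 %, 10 % in-mask pixel sets, averaged over the three fractions
(ties break by flat pixel index; for independent maps the expected Dice at
fraction f is f, which the Monte-Carlo tests confirm). Cross-model
consistency: Spearman correlation (average ranks for ties) of in-mask
|saliency|. Focus: Shannon entropy (natural log — the base is a
convention and is recorded here) of the probability vector formed from the
top 10 % of in-mask pixels; non-positive mass falls back to uniform with a
warning. Drift: Euclidean displacement of that probability map's centre of
mass between consecutive loops; missing intermediate loops skip the step.
Region votes: SLIC superpixels (50 segments, compactness 0.1, clipped to
the mask; the algorithm is pluggable) scored by mean z-scored saliency per
method; the top 10 % of region scores (minimum one) receive the method's
vote, and the fractions of regions voted by ≥ 2/3/4 methods are reported.
Maps live in an HDF5 store grouped
/experiment/well/loop/model/method/condition.

## Problem sizes

The desk-scale study used by the test suite and the acceptance script is 3
experiments × 24 wells × 36 loops at 96-px frames (~2,600 accepted frames
through the full segmentation + morphometrics chain), with heterogeneity
curves from 1 × 24 × 36 and quantification checks at 256-px rasters; these
sizes were chosen so every end-to-end property is exercised on a single
CPU in minutes while keeping ≥ 20 organoids per class per fold. Frame
rasters below ~192 px make the segmentation IoU discretisation-bound
(≈ 0.88 at 96 px vs ≥ 0.94 at 256 px), so mask-accuracy checks use the
larger rasters and the prediction studies use the small ones.

## Known limitations

- The default segmenter assumes one dark object on a bright background;
  frames dominated by a bright lens can fail QC (by design they are
  rejected, not mis-measured).
- Local thresholding cannot recover large *uniformly mid-dark* patches;
  pigment quantification relies on pigment being near-black after in-ROI
  rescaling.
- The numpy CNN is a correctness- and contract-oriented reference model,
  not a performance model; real studies would plug in a GPU-trained
  network behind the same interface.
- The 165-feature registry pins *a* composition satisfying the named
  descriptor set and the count; other compositions are possible, which is
  why the registry is versioned and persisted alongside feature tables.
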