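# Methods

## The detection model

`symstrain` detects focal muscle-strain lesions in bilateral B-mode
ultrasound pairs with a two-stage, symmetry-aware cascade.

**Stage 1 — anchor-based proposals.** A single-class detector predicts
boxes on three feature maps downsampled 32×, 16× and 8×, with three
anchors per grid location. Each anchor emits 4 box coordinates, 1
objectness logit and 1 lesion-vs-background logit, so every head produces
`3 × 6 = 18` channels. Box centers decode as `2·σ(t) − 0.5` cell offsets
(range (−0.5, 1.5), so a neighboring cell can own a box) and sizes as
`anchor · exp(t)`. A ground-truth box is assigned to the anchor with the
highest shape-IoU (plus all anchors above IoU 0.5) at its center cell and
that cell's two nearest neighbors. Anchor sizes default to k-means over
the training set's box sizes (9 clusters, largest three to the coarsest
head). Inference letterboxes the image to the configured input size,
decodes all grids above the confidence floor, keeps the top 300 and
applies greedy NMS (IoU 0.30). Confidence is `σ(objectness) · σ(class)`.

The backbone is deliberately small — five strided conv blocks with one
residual block per resolution — because the cascade's claims concern the
head geometry and the routing/verification policy, not the trunk; the
pipeline is detector-agnostic by construction.

**Stage 2 — routing and contralateral verification.** With thresholds
`T1 < T2` (defaults 0.01 / 0.20), detections below `T1` are suppressed and
those at or above `T2` accepted. The band `[T1, T2)` is verified: for each
forwarded box the four candidate reference patches on the opposite side —
the exact mirrored center plus three jitters drawn without replacement
from `{−32, 0, +32}² \ {(0,0)}` — are cropped at 128 × 128 px, flipped
back into the index side's orientation (the two sides are mirror images
under standardized bilateral acquisition), and scored by the similarity
network. Under the default `all_dissimilar` aggregation a detection
survives only if *every* reference scores dissimilar: a genuine unilateral
lesion matches none of the contralateral candidates, while a bilateral
look-alike that matches any of them is an artifact. `best_reference`
(HOG-closest candidate decides) and `majority` (≥ 3 of 4) are provided
because the combination rule is a genuinely open design choice.

**HOG reference localization.** Patches are compared with dense HOG
descriptors: centered-difference gradients with zeroed borders, unsigned
orientations folded to [0°, 180°), 9 bins, 8 × 8 cells, 2 × 2-cell blocks
at 1-cell stride, L2-Hys normalization (L2, clip 0.2, re-L2). Orientation
votes use hard binning — the convention of the scikit-image reference
implementation, against which the descriptor is verified to ~1e−6 — rather
than bilinear interpolation. Descriptor distance is Euclidean. The
per-pixel "HOG map" channel is defined as per-cell gradient energy (L2
norm of the cell's normalized histogram averaged over the blocks that
contain it), nearest-neighbor-upsampled and rescaled to [0, 1]; an energy
map was chosen over a dominant-orientation map because the verification
task needs texture presence, not fiber direction, and the channel is
config-switchable (`channel_mode="grayhog_pair"`).

**Similarity network.** The default input stacks the index patch and its
reference patch as 2 channels (optionally + both HOG maps = 4). This
composition is what makes the random left/right channel-swap augmentation
meaningful. A compact pre-activation residual CNN (stride-2 conv + BN +
ReLU + residual block per stage; global average pooling; linear; tanh)
maps the pair to one score in [−1, 1], trained with MSE against labels
−1 (similar) / +1 (dissimilar) under the patch augmentations: rotation
±5°, isotropic scale 0.9–1.1, photometric jitter ±10%, Gaussian noise
σ ∈ [0.01, 0.02], channel swap p = 0.5. The decision threshold is 0 (the
sign of tanh) with the boundary tying toward "dissimilar", a
recall-preserving choice. Classes are rebalanced per epoch by oversampling
the minority class (capped at 4× the minority size).

**Training-pair mining.** A 128 px window slides at stride 64 over each
side image (= hemifield). Per window the reference is refined among the
four mirror/jitter candidates by HOG distance. Labels: window center
inside a ground-truth box with a lesion-free refined reference → +1;
no ground-truth overlap on either side → −1; anything ambiguous
(overlap without center containment, or lesions on both ends) is
discarded. The labeling rule is our construction; mining geometry
(stride, patch, jitter) is fixed by the protocol.

## Evaluation protocol

Detections are matched to ground truth one-to-one, greedily in descending
confidence, at IoU ≥ 0.5 (configurable); unmatched predictions are FP,
unmatched truths FN. Precision 0/0 is defined as 0 with a warning. Fβ is
`(1+β²)PR/(β²P+R)`; F2 weights recall four times as heavily as precision.
Average precision uses the all-point interpolated precision envelope over
the pooled ranked detections of all images; with one foreground class,
mAP = AP. Splits are patient-level: hold-out patients are removed first
(greedily until the requested pair count), the rest shuffle into k folds,
and both sides of a pair always travel together. Confidence intervals are
percentile intervals from a patient-level bootstrap stratified by
lesion-positive status, recomputing the metric from pooled TP/FP/FN per
resample. Cohen's and Fleiss' κ implement the textbook formulas (with
explicit degenerate-case contracts) and are cross-checked against
scikit-learn and statsmodels in the tests. `threshold_sweep` re-partitions
stored raw detections over a T1 grid with T2 fixed, with and without the
verification stage, without re-running any model.

## The phantom generator

Real data cannot be redistributed, so all experiments run on synthetic
bilateral speckle phantoms that emulate exactly the structure the cascade
assumes:

- a smooth low-frequency anatomy field plus horizontal sinusoidal
  striation bands (period `striation_period`, default 24 px) emulating
  hyperechoic connective tissue;
- the right side is the horizontal mirror of the left, translated by a
  Gaussian offset (`side_offset_sd`, default 4 px) emulating probe
  entry-point deviations;
- multiplicative speckle per side: the envelope of complex Gaussian noise
  low-pass filtered at `speckle_scale` (default 3 px), a standard
  Rayleigh-like B-mode surrogate, drawn independently per side;
- lesions: hypoechoic ellipses (semi-axes 10–26 px, interior intensity
  reduced by `lesion_contrast`, default 0.5) that zero the striation
  locally (fiber discontinuity), each placed on exactly one side, with
  tight axis-aligned ground-truth boxes;
- bilateral distractors (default 2 per pair): symmetric hypoechoic spots
  stamped before mirroring, present on both sides and excluded from
  ground truth — these give the verification stage its true negatives.

What the phantom does **not** model: wave propagation, attenuation,
anisotropy artifacts, Doppler, real fascicle geometry, scanner or operator
variability. Passing tests therefore demonstrate that the cascade
mechanics work when the mirrored-anatomy assumption holds to within a
translation; they are not evidence about clinical images. No quantitative
lesion-appearance statistics were available to calibrate against, so the
phantom defaults are generic plausible values, fixed once, not fitted.

## Problem sizes and numerical choices

The package ships two config profiles. The faithful profile keeps the
published geometry (544 px detector input, 1000 filter epochs). The
desk-scale profile — used by the tests, the README example and all
reported numbers — trains on 256 px phantoms: detector input 256 (grids
8×8 / 16×16 / 32×32), 30 training pairs × 60 epochs for the detector; the
filter trains 30 epochs on ~240 pairs mined from a lesion-rich 120-pair
cohort (4 lesions per pair, semi-axes 14–34 px, chosen so the coarse mine
yields roughly class-balanced labels; evaluation cohorts keep the default
conditions). Held-out evaluation uses 30 pairs from unseen patients with
fixed seeds.

Numerics worth knowing:

- Both networks run on a self-contained float32 numpy layer stack
  (im2col convolution, hand-derived backward passes verified by finite
  differences, Adam). With no GPU framework in the dependency set this
  keeps the package hermetic and the training loops transparent.
- Detector loss: binary cross-entropy on objectness with negatives
  normalized *within each pyramid level* (so the coarse 8×8 grid is not
  drowned out by the 16× larger fine grid) and weighted 4× relative to
  positives; squared error (weight 5) on encoded box offsets; BCE on the
  class logit of positives. A squared-error box loss was preferred over an
  IoU-family loss to keep the hand-written gradients simple; on phantom
  boxes the two differ little.
- The similarity filter uses batch normalization; the detector trunk does
  not (its per-level-balanced loss trains stably without it, and skipping
  batch statistics keeps single-image inference identical to training
  behavior).
- Determinism: every stochastic step (phantom synthesis, jitter draws,
  shuffling, init, augmentation) flows from explicit integer seeds;
  identical seeds reproduce identical phantoms bit-for-bit and identical
  training traces on one machine.
- Degenerate inputs: zero-gradient images yield all-zero HOG blocks (no
  division blow-up, eps = 1e−5); out-of-image patch crops reflect-pad;
  empty prediction sets yield precision 0 with a warning; bootstrap
  resamples with undefined metrics are redrawn and logged.

## Known limitations

- The phantom's mirrored-anatomy assumption is much cleaner than clinical
  reality; absolute metric values on phantoms do not transfer.
- The hand-written training stack is single-threaded CPU code; the
  faithful 544 px / 1000-epoch profile is provided for completeness but is
  slow at desk scale.
- The verifier sees only translation jitter (±32 px); rotational or
  elastic inter-side misalignment is out of scope, as is whole-image
  sliding-window search at inference.
- Probabilistic fusion of detector confidence and similarity score, and
  lesion grading, are intentionally not implemented.
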