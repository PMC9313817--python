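# Methods

`muscleseg` re-creates, at desk scale and on fully synthetic data, a
transfer-learning study of data-efficient skeletal-muscle segmentation on
axial CT slices at the L3 vertebral level: pre-train on a source task,
transfer weights by layer name into a target segmentation network,
fine-tune on nested training subsets of increasing size, and compare
segmentation accuracy and extracted muscle characteristics against a
simulated inter-observer baseline.

## Synthetic phantom

Each phantom is a single 2-D slice (default 128 px at 3 mm isotropic
spacing; the desk-scale experiment configurations use 64 px at 6 mm so that
the field of view stays ~384 mm) containing:

* an elliptical body filled with fat-like tissue (mean −100 HU),
* a ring-shaped skeletal-muscle compartment hugging the body wall
  (mean 45 HU, within-patient SD 10 HU) whose outer radius, inner radius
  and circumferential thickness profile are perturbed per patient by
  random-amplitude, random-phase angular modes up to order 7
  (`shape_variability`, default 0.14),
* a visceral soft-tissue region (mean 30 HU) filling the cavity and
  touching the ring directly — the inner muscle boundary is therefore a
  low-contrast interface, as in real anatomy,
* 4–7 "organ" discs at muscle-equivalent attenuation inside the cavity,
  most touching the inner wall, so that intensity alone cannot separate
  wall muscle from adjacent viscera,
* a vertebral body plus 1–3 posterior bone elements (mean 450 HU,
  guaranteed above the 175 HU bone threshold), and
* additive Gaussian noise (default SD 12 HU).

Per-patient attenuation shifts (SD 12 HU) are applied to the muscle,
visceral and fat means, mimicking the clinical spread of muscle quality
(myosteatosis) across a cohort; absolute HU is deliberately an unreliable
cue. High-frequency shape modes are used because inter-patient anatomy is
not reducible to the augmentation group (rotations/flips/scalings) — a
model cannot generalize across patients merely by learning augmentation
invariance.

What the phantom does **not** emulate: organ texture, PET channels, 3-D
context, partial-volume gradients at boundaries, and pathology. Passing
results therefore demonstrate that the pipeline's machinery (design,
transfer, optimization, metrics, statistics) behaves correctly at realistic
geometry and contrast, not that any specific clinical accuracy would be
attained on patient data.

## Simulated observers

Observer delineations displace the true boundary by a Gaussian random
field, smoothed to a 20 mm correlation length along the image and scaled to
an RMS amplitude in mm, plus an optional signed systematic bias: the new
contour is the level set `d(x) ≤ noise(x) + bias` of the signed distance
d to the true boundary. Correlated noise is essential — independent
per-pixel label noise cannot produce the contour-level agreement
(Dice ≈ 0.90) reported between trained human observers. The amplitude is
calibrated by bisection against a requested mean DSC (deterministic
sub-seeds make the objective monotone in amplitude); calibrated panels
reproduce the target within ±0.01 and land inside the 0.88–0.92 band used
as the human-performance reference. Five observers per test image are
simulated; with the expert mask this yields six delineations per image.
The expert (ground truth) is treated as optimal; expert intra-observer
variability is not modelled.

## Networks and training

No GPU framework is assumed: `muscleseg.nn` is a compact CNN stack in
numpy (float32) with hand-derived backward passes, verified against
central differences at ~1e-6 relative error in float64. One residual
encoder family (stem → two stride-2 stages with residual blocks; ~35k
parameters at width 8) is shared by all tasks; a nearest-upsample decoder
restores full resolution. An optional parameter-free instance
normalization exists behind `NetConfig.use_norm` (default off).

The four pre-training source tasks:

* **reconstruction** — autoencoder minimizing MSE on the training slices;
  encoder weights are transferable.
* **jigsaw** — slices are cut into a 3×3 grid, shuffled by one of 50
  permutations, and a Siamese network (nine weight-shared encoder branches,
  concatenated pooled features, classification head) predicts the
  permutation. The 50 permutations are chosen greedily to maximize mean
  Hamming distance to the already-selected set, starting from the
  permutation farthest from the identity, ties broken lexicographically.
* **classification** — encoder + global-pool + linear head on image-level
  labels supplied by the generator; a desk-scale stand-in for natural-image
  classification pre-training (externally trained weights can be loaded
  through the same NamedWeights interface).
* **segmentation** — an encoder–decoder segmenting the abdominal *wall*
  compartment (body minus cavity = muscle + subcutaneous fat) on a disjoint
  auxiliary cohort with different shape statistics. The wall was chosen
  over alternatives (fat compartment, cavity) because its inner boundary
  poses the same boundary-completion problem as the target ring; at this
  network capacity a more distant dense task transfers no measurable
  signal. Since source and target share the whole topology, the full state
  including the 1-channel head is emitted, and every layer present in both
  transfers.

Weight transfer copies a source array into the target iff layer name and
shape both match; mismatches are recorded, never fatal. Unmatched layers
get fan-in-scaled uniform weights and zero biases, seeded per run.

Fine-tuning uses Adam (β = 0.9/0.999, batch 8, no weight decay), an
initial learning rate of 3e-3 for fully random initializations and 3e-4
whenever any weights were transferred, augmentation redrawn every epoch
(horizontal flip, rotation ±20°, elastic deformation, scaling 0.9–1.1,
each independently with probability 0.5; images bilinear, masks
nearest-neighbour), and early stopping with patience 20 on the validation
loss (desk-scale grids use patience 40 with a 150-epoch cap; the
data-efficiency experiment instead fixes the optimizer-step budget at 120
steps per run so that different subset sizes receive equal optimization).
The checkpoint is the state at minimum validation loss. The training loss
is per-sample BCE (pixel-mean, probabilities clamped at 1e-7) plus soft
Dice (ε = 1e-7), averaged over the batch. Predictions are
sigmoid-thresholded at 0.5 with ≥ mapping to foreground.

## Metrics

* **DSC** 2|A∩B|/(|A|+|B|); two empty masks agree (1.0) by convention.
* **RMS-DTA** root mean square, over the K points of the *predicted*
  boundary (foreground pixels 4-adjacent to background or image edge,
  coordinates in mm), of the Euclidean distance to the nearest reference
  boundary point, reported in cm. The direction is asymmetric
  (predicted → reference), matching the normalization by the predicted
  boundary's point count; a literal variant that squares the difference of
  the forward and backward nearest distances is available behind
  `formula="printed"` for comparison — it collapses toward zero for
  symmetric contour mismatches and is not used for analysis.
* **Bone post-processing** threshold at 175 HU, dilate with a digital disc
  of radius 2 mm (rounded to pixels), subtract from predictions before
  extracting muscle density.
* **SMD** mean raw (unwindowed) HU inside the mask; **SMA** foreground
  pixel count × pixel area in cm².

Both metrics are verified exactly against brute-force oracles (direct
pixel counting; all-pairs nearest distances) on random masks up to 16×16.

## Study design

A held-out test set (paper-shaped default 37 of 204) is annotated by the
simulated observer panel; the remaining ids are split into 4 folds. Per
fold, the other folds' union is subsampled into nested subsets
(5 ⊂ 10 ⊂ 25 ⊂ … ⊂ 125): each larger subset extends the smaller, isolating
sample-size effects from sample identity. Two independent subset chains per
size and two training repeats per subset give 16 runs per
(source task, size) cell. Per-run seeds are derived by hashing the master
seed with the run coordinates. Whether subset chains are shared across
folds is not prescribed anywhere; they are drawn per fold here.

Summaries report per-cell means with normal-approximation 95% CIs over all
predictions; Dunnett's many-to-one test (via the multivariate-t reference
distribution, pooled variance) compares each cell against the pooled
per-contour observer values, two-sided, with per-prediction pooling as the
default unit of analysis (per-run means are available since the
aggregation unit is a genuinely open choice). Degenerate all-identical
inputs return p = 1 by convention. The family-wise error of the wrapper is
Monte-Carlo-calibrated at α = 0.05 in the test suite (10,000 null
replicates, k = 3).

## A negative result, documented deliberately

At this scale the package's experiment does **not** reproduce the
qualitative finding that dense-task pre-training beats random
initialization at n = 5. Across every configuration we examined (harder
and easier phantoms, three auxiliary source tasks, widths 8/16, batch
sizes 2/8, with and without normalization, budgets up to full saturation),
scratch training at 3e-3 matched or out-performed transfer at 3e-4
(typically ≈0.75–0.79 vs ≈0.70–0.76 mean test DSC at n = 5). Two
mechanisms explain this. First, Adam's parameter travel is roughly
lr × steps, so at a matched step budget the transferred arm explores a
tenth of the distance; long runs show it converging into the source task's
basin rather than merely lagging. Second, the augmentation suite spans
much of a small phantom family's inter-patient variability, so five
augmented images already suffice for a ~35k-parameter network — consistent
with the observation in the source literature that augmentation, not
transfer alone, drives small-n performance. The benefit of large-scale
dense pre-training appears to be an emergent property of much larger
model capacity. The data-efficiency experiment, its fixed-step-budget
policy, and the directional assertion are retained unchanged so the result
is measured, not assumed; the monotone improvement of DSC with training-set
size does hold for every source task.

## Numerical choices

* Probability clamp 1e-7 in BCE; ε = 1e-7 in Dice denominators.
* Binarization threshold 0.5, ≥ convention.
* Empty-vs-empty DSC 1.0; empty predictions record no RMS-DTA (NaN row).
* Degenerate phantom draws (empty muscle, no supra-threshold bone) are
  regenerated from perturbed sub-seeds, at most 5 attempts, logged.
* Observer calibration bisects amplitude on [0, 30] mm, tolerance 0.005
  in mean DSC, 50 iterations max.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; single-threaded numpy keeps every stage
  bit-reproducible.

## Known limitations

Phantoms are 2-D and texture-free; observer bias is a single global
inward/outward term; the classifier proxy's labels (bone-component count
or intensity classes) are far simpler than natural-image classes; the
paper-shaped full grid (5 source tasks × 7 sizes × 16 runs) takes hours on
one CPU core, so the default configurations shrink the grid, image size
and epoch budgets as stated above.
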