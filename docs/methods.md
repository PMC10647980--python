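# Methods

## Problem and study design

Radiotherapy planning requires delineating thoracic organs at risk —
the paired lungs, the heart, and the spinal cord — on CT. Convolutional
segmentation networks are usually trained on supine (unrotated) scans,
so a patient rotated in the transverse plane presents an input the model
has never seen. This package studies whether *jointly* learning to
segment spatially-correlated neighboring organs (SCOS: one shared
encoder–decoder backbone with one sigmoid head per organ) is more robust
to such rotations than single-task learning (STL: one network per
organ), than two published multi-task settings with shape-prior
auxiliary heads, and than explicit rotation augmentation.

The protocol is strict about rotation leakage: all training and
validation data are unrotated; rotation only ever appears (a) in the
test sets, and (b) inside the online augmentation of the `*_aug`
settings. The training loop audits this (a rotated slice in a
non-augmented stream is an error).

Four task settings share one backbone:

| setting | heads | loss |
|---|---|---|
| STL_{organ} | 1 sigmoid | −mean Dice |
| SCOS | 3 sigmoid (lung, heart, cord) | −mean ΣDice |
| TASKS1 | 3 sigmoid + 1 linear distance | SCOS loss + distance MSE |
| TASKS2 | TASKS1 + 3 sigmoid contour | + contour Dice loss |

The distance-map target is, per organ, the Euclidean distance of each
interior pixel to the organ boundary, normalized by that organ's
maximum, summed across the three (disjoint) organs into one channel in
[0, 1]. The contour target is each organ's binary edge (mask minus its
8-connected erosion).

## Backbone

A classic U-net contraction/expansion: per level two 3×3 same-padded
convolutions with ReLU; 2×2 max-pool downsampling; 2×2 stride-2
transposed convolutions for upsampling; skip concatenation; two 3×3
convolutions per decoder level; each head a 1×1 convolution. Filters
double per level. The network, its backpropagation (including the guided
variant), and Adam are implemented in NumPy inside `scos.nn`; gradients
are verified against central finite differences in float64 (relative
error ≤ 1e−5 across all layer types).

Desk-scale defaults: depth 3, 6 base filters, 56×56 study inputs
(64×64 phantom default elsewhere; the construction generalizes to any
depth/width with divisible input sizes). Weight initialization is He-uniform from a seeded
generator. Two initialization choices matter and are deliberate:

* **Sigmoid heads start at bias −2.** With a soft-Dice loss and heads
  initialized at p ≈ 0.5 everywhere, the Dice denominator Σp + Σt is
  dominated by the ~4096-pixel prediction mass, so the gradient on a
  ~13-pixel structure (spinal cord) is diluted by two orders of
  magnitude and the cord head does not converge in any reasonable
  budget. A negative bias makes the initial foreground sparse
  (σ(−2) ≈ 0.12), restoring the gradient scale. This is the standard
  sparse-foreground prior initialization for imbalanced dense
  prediction.
* **The linear distance head starts at zero.** A randomly initialized
  regression head floods the shared backbone with large noise gradients
  during the critical early epochs; empirically this permanently traps
  the cord segmentation head even when the regression term itself is
  small. Zero weights make the auxiliary gradient ramp in as the head
  learns.

## Losses

Dice terms use the soft form 2Σpt / (Σp + Σt) with a smoothing constant
of 1e−6 for empty-mask stability; evaluation-time Dice uses hard masks
and no smoothing. Setting totals are plain unweighted sums of their
terms — no task weighting.

The distance term is the squared error between predicted and true
distance maps. The `loss_distance` function reports the per-image *sum*
of squared errors by default; the training loop uses the per-pixel
*mean* (a pure rescale of the same objective, and the convention of the
mse losses in mainstream frameworks). The rescale matters: with the raw
sum (hundreds at initialization on these image sizes, against Dice terms bounded
by 3) the regression gradient monopolizes the shared backbone and the
segmentation heads of TASKS1/2 never converge at desk scale; with the
per-pixel mean they converge indistinguishably from SCOS.

Training: Adam, batch size 8. The reference full-scale recipe (learning
rate 1e−3, 3000 epochs) is kept as the default of record; the desk-scale
study uses learning rate 4e−3 with a 34-epoch base budget, chosen by
profiling convergence. Augmented settings draw a fresh uniform angle in
[−30°, 30°] per sample per epoch (online augmentation — the training
set is never inflated).

Soft-Dice optimization of very small structures is *bistable*: some
weight draws leave a head saturated at an empty prediction (all logits
driven far negative by the background majority, so the sigmoid gradient
on the few foreground pixels vanishes). Longer training does not rescue
such basins. The trainer therefore carries two seed-deterministic
safeguards, both decided from training-Dice traces on probe runs:

* **restart** — if any segmentation head's training Dice is below 0.30
  at epoch 21, training restarts from a fresh init derived from the
  seed (up to three times; if every attempt is stuck, the most
  promising one is resumed);
* **extension** — after the scheduled epochs, while any head's training
  Dice is below 0.90, training continues in blocks of 8 epochs (at most
  two blocks).

Both act only on *training* quantities, never on validation or test
data, and derive all randomness from the replicate seed, so a rerun
with the same seed is bit-identical.

## Evaluation metrics

Per (case, organ): hard Dice, maximum Hausdorff distance (maxHD),
95th-percentile Hausdorff distance (95%HD), average surface distance
(ASD), and across cases N(inf), the number of cases with an empty
prediction against a nonempty truth (total recognition failure; all
surface distances are infinite there, and such cases are excluded from
quartile summaries but reported as N(inf)).

Surface distances are nearest-neighbour Euclidean distances between
*contour* pixels (mask minus erosion, 8-connectivity in 2D, 26 in 3D),
pooled over both directions; maxHD is the maximum, 95%HD the linearly
interpolated 95th percentile, ASD the pooled mean. KD-trees provide the
nearest-neighbour queries; the test suite checks exact agreement
(≤ 1e−9) with a naive all-pairs oracle on hundreds of random mask
pairs. Distances are in pixels by default and in mm when a voxel
spacing is supplied. An empty *truth* mask makes the metrics undefined;
such organs are skipped rather than scored (arises only at the apex/base
slices of 3D stacks).

3D evaluation optionally keeps only the largest 26-connected component
of each predicted organ volume first (clinical post-processing); ties
resolve deterministically to the first component in raster order. The
quartile summaries report Q1/median/Q3/IQR/mean over finite values plus
N(inf), matching the boxplot conventions used for this kind of study.

## Phantom generator

No public CT cohort backs this study, so a seeded generator produces
thorax-like labeled slices: a soft-tissue body ellipse on an air
background; two air-intensity lung ellipses (the left field placed
slightly higher than the right, as in real anatomy) with a concave
medial border carved by a mediastinal stripe; a heart ellipse centered
on the midpoint of the lung centers (so its centroid falls inside the
lung-centroid bounding box — the spatial-correlation property the joint
setting exploits); and a small cord disc inside a bright vertebral ring
on the posterior midline. Intensity levels approximate CT: air −1000,
lung −700, soft tissue/heart 40, cord 30, vertebral bone 400 HU, plus
Gaussian noise (σ = 20 HU), so the −135…215 HU display window is
meaningful. Heart and mediastinum share the same intensity — as on real
CT, the heart boundary must be inferred from context, which is exactly
the cue structure the study is about.

Rotation is applied to the analytic shape parameters *before*
rasterization, so ground-truth masks are exact at every angle (no label
resampling error in the test sets). Augmentation-time rotation of
training samples, by contrast, resamples images bilinearly and masks by
nearest neighbour, as a real pipeline would.

3D stacks scale organ sizes smoothly along the stack: the cord runs
through every slice, lungs and heart occupy contiguous central runs and
vanish at the first/last slices. Test volumes are rotated by a uniform
draw from ±[1.5°, 9.34°], the range reported for genuinely rotated
patients in the clinical setting this emulates.

What the phantom does **not** model: anatomical shape variability beyond
ellipse parameter jitter, pathology, partial volume effects, scanner
artifacts, or DICOM semantics. Passing the comparative checks on
phantoms demonstrates the *mechanism* (joint learning of co-located
structures improves rotational robustness under these contrasts), not
clinical performance.

## Desk-scale study conditions

Chosen by profiling convergence (validation-Dice plateau) on a single
CPU and then frozen: 56×56 phantoms (the spinal-cord disc keeps its
absolute pixel size); depth-3 backbone with 6 base filters; 64 training
and 32 validation slices (unrotated); 72 rotated test slices; 2 test
volumes of 9 slices; learning rate 4e−3 for a 34-epoch base budget with
the restart/extension safeguards; three seeds. Each
seed trains ten models (three STL, SCOS, TASKS1, TASKS2, three STL_aug,
SCOS_aug); the whole study runs in roughly a quarter hour. The
train:test imbalance of the full-scale protocol (small training set,
large rotated test set) is kept directionally.

## Saliency and receptive fields

* Gradient map: |dS/dI| with S the sum of one head's output
  probabilities, max-normalized for display.
* Guided grad-CAM: the elementwise product of a guided-backpropagation
  input gradient (backward pass rectified at every ReLU) and the
  rectified gradient-weighted channel sum of a chosen layer's
  activations, bilinearly upsampled. The scalar target is the sum of
  head probabilities over the predicted region (≥ 0.5), falling back to
  all pixels when the prediction is empty. The CAM layer defaults to the
  last decoder convolution.
* Average feature map: channel mean of a layer's activation,
  interpolated to input size, optionally alpha-blended with the input.
* Receptive fields are computed analytically by interval recursion over
  the layer chain (3×3 same convs widen by 1 per side; pools double and
  widen; transposed convs halve), walking the deepest encoder–decoder
  path — the skip branches' fields are strict subsets. The test suite
  verifies jointly with the network wiring that input gradients vanish
  exactly outside the analytic box.

## Numerical conventions and degenerate inputs

Percentiles use linear interpolation between order statistics. Mask
thresholding is boundary-inclusive at 0.5. The network trains in
float32; metrics and targets are computed in float64; the whole network
can be cast to float64 for verification. Empty organ masks contribute
zero to the distance map (no division by zero); an empty contour arises
only from an empty mask. Connected-component ties and pooling-argmax
ties resolve to the first candidate in raster order, keeping every
pipeline stage bit-reproducible under a fixed seed.

## What the desk-scale study shows — and what it does not

Running the study (`run_study(desk_study_config(...))`, which is exactly
what `scripts/acceptance.py` does) reproduces the *infrastructure* of
the comparison and part of its substance: every task setting trains to
high unrotated-validation Dice; rotation degrades all settings; online
rotation augmentation restores spinal-cord robustness to the joint
model in every replicate.

The clinical study's headline ordering — joint learning more
rotation-robust than single-task learning — does **not** emerge on this
phantom; the runs here consistently show the opposite, with the joint
model contributing the empty-prediction failures under rotation. The
reason is instructive. The phantom gives every organ a locally
unambiguous, rotation-invariant appearance cue (air-intensity lung
fields; the bright vertebral ring around the cord), so a single-task
model that keys on local appearance is already rotation-robust. The
joint model leans on inter-organ context — the very spatial correlation
it is designed to exploit — and that context is position-dependent,
hence fragile under ±30° rotation. On real CT the cue structure is
reversed: local appearance is ambiguous (similar-looking tissue occurs
in many places, which is precisely what produces single-task false
positives), and contextual knowledge of neighboring organs is what
disambiguates. A phantom with engineered local ambiguity (decoy
structures) would likely reproduce the clinical ordering, but that
would amount to building the answer into the data generator, so the
generator was frozen at its design and the comparison is reported as
measured. The practical reading: which learning setting is more
rotation-robust depends on whether local appearance or spatial context
is the more reliable cue in the data at hand.

## Known limitations

The NumPy backbone is CPU-bound, which caps the affordable problem size
well below the full-scale protocol; headline clinical numbers (e.g.
N(inf) counts on thousands of real slices) are out of reach by design.
The phantom's narrow shape distribution makes absolute Dice values
optimistic relative to clinical data; only the *orderings* between
settings are meaningful. Batch normalization, dropout, 3D convolutions
and pretrained encoders are deliberately absent.
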