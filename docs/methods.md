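# Methods

`radview` is a desk-scale, end-to-end pipeline for classifying the view
orientation (frontal vs lateral) of chest radiographs. It reproduces the
*methodology* of high-throughput view classification — preprocessing,
heavy label-preserving augmentation, leakage-safe splitting, transfer
learning with distinct fine-tuning regimes, Youden-Index cutoff selection,
and exact binomial intervals — on procedurally generated phantom
radiographs, so every stage is testable on one CPU without any image
download.

## Phantom radiographs (synthetic_data)

Phantoms are stylized, not anatomical: a frontal view is two laterally
symmetric dark elliptical "lung fields" flanking a bright central
mediastinal/vertebral column (grey levels 60 / 220 on a 150 background); a
lateral view is a single large dark lung region with a bright column near
one lateral (posterior) edge. View discrimination is a geometry task, and
the phantoms preserve exactly the geometric cues that distinguish real
frontal from lateral radiographs — bilateral mirror symmetry and column
position — which is what makes them a meaningful stand-in.

Corruption model: additive Gaussian pixel noise (default sd 8 grey levels),
optional rotation jitter (degrees) and multiplicative intensity jitter. At
noise sd ≤ 16 a trivial statistic (mean column-wise left/right mirror
correlation) already separates the classes, so any competent learner has
signal; the tests verify this with a brute-force pixel-loop oracle.

Cohorts are patient-structured: each synthetic patient contributes 1–2
images (studies), each labeled frontal with probability 2/3 by default —
two-view studies contribute one image of each view while single-view
studies are usually frontal, so a two-thirds frontal share is a realistic
default for a mixed archive; it is configurable. What the phantoms do *not*
emulate: pathology, devices, exposure artifacts, burned-in annotations, and
inter-patient anatomical variation. Passing tests therefore demonstrate the
pipeline's correctness and the qualitative transfer/augmentation effects,
not clinical-grade accuracy on real radiographs.

## Preprocessing

Raw intensities (8-bit PNG/JPEG or monochrome DICOM pixel arrays) are
min-max windowed: the observed [min, max] is mapped linearly onto [0, 255]
with round-half-even quantization. A constant image maps to all zeros (any
constant is information-free, so the convention is arbitrary but fixed).
Images are then squash-resized to a fixed square (default 256×256) with
bilinear interpolation and no anti-aliasing filter, deliberately not
preserving aspect ratio. Windowing precedes resizing; both steps are
deterministic and the window step is idempotent on its own output. Color
inputs are collapsed by Rec. 601 luma before windowing. Internal storage is
lossless PNG so pipelines stay bit-exact; a JPEG export flag reproduces the
lossy archival format when wanted.

## Augmentation

Six operator families: horizontal/vertical reflection; rotation by ±2°
(bilinear, zero fill) or ±90° (exact index permutation); 3-pixel
translation along the 8 compass directions (zero fill); pixel spread
(raster-order swap of each pixel with a uniformly chosen 8-neighbor,
seeded — value multiset is preserved); median offset (replace each pixel by
the order statistic one rank before/after the median of its square
neighborhood of radius 2 or 5, truncated at edges); and random noise
(seeded salt-and-pepper at 1% of pixels — an impulse model was chosen
because it is the common "random noise addition" in image toolkits and is
exactly countable in tests).

The default plan emits exactly **106** distinct, non-identity children per
parent: the grid {identity + 14 geometric} × {identity + 6 photometric}
minus the identity×identity cell (104), plus two documented extras
(hflip∘vflip, i.e. 180° rotation, with and without pixel spread). The
combination recipe is a design choice of this package — the operator
families and the total are fixed, the grid is how this artifact reaches
that total — and plans are plain data (tuples of `TransformSpec`), so an
alternative recipe is a configuration change. Children inherit label,
patient, study and split from the parent; per-child seeds derive from
(base seed, parent id, spec index) via CRC32, so augmentation is
bit-reproducible. Augmented sets contain children only: 1129 parents × 106
= 119,674 and 376 × 106 = 39,856.

## Splitting

Splitting precedes augmentation (enforced: augmented records are rejected),
so siblings can never straddle splits. Sizes follow floor-floor-remainder:
floor(0.6·1882)=1129 train, floor(0.2·1882)=376 validation, remainder 377
test. The default split is image-level; `patient_stratified=True` keeps all
images of a patient in one split (sizes then approximate the fractions),
for archives where patients contribute multiple images.

## Training harness

No neural-network framework is assumed: the model is a compact CNN written
directly in numpy — three 3×3 conv + ReLU + 2×2 max-pool blocks (8/16/32
filters, the *extractor*) and two fully connected layers (hidden width 32,
the *head*), softmax output. Float64 arithmetic with per-image forward
passes makes training bit-deterministic under a seed and makes batched
inference exactly equal to one-at-a-time inference. The extractor/head
boundary is the parameter-name prefix (`conv*` vs `fc*`), so regime
semantics are exact:

* **fc_only** — extractor frozen (its tensors are never written; bit
  identity is asserted in tests), base learning rate 0.005;
* **all_layers** — everything trainable, base learning rate 0.0005. This
  regime is rejected without an augmented fine-tuning set (too few images
  relative to trainable parameters).

Optimizer: SGD with Nesterov momentum (PyTorch-style formulation
`v ← μv + g; p ← p − lr(g + μv)`), momentum 0.9, weight decay 5e-4,
mini-batch 24, 30 epochs by default, learning rate reduced tenfold every
ten epochs (`lr(e) = base_lr · 0.1^⌊e/10⌋`, epochs 0-based; the recorded
per-epoch rate is part of the training history). Loss is two-class
cross-entropy. Inputs are scaled to [0,1] and the training-set mean is
subtracted; the mean is stored on the model so prediction does not depend
on the composition of the evaluation batch.

Pretraining uses a generic two-class shape-discrimination set (discs vs
square frames) as the stand-in for a large non-radiology corpus, in
greyscale or color; a color-pretrained model is adapted to greyscale input
by averaging the first conv layer's input-channel kernels (a standard
channel-collapse; retraining from the adapted state is what fine-tuning
then does). At fine-tuning the head is re-initialized (seeded) for the
frontal/lateral task and the extractor is carried over.

The paper-scale settings (30 epochs, batch 24, 256×256 inputs) are the
defaults; tests and the acceptance script run the same code path at reduced
sizes chosen for single-CPU speed — 64×64 phantoms, 150 generic images per
class with 3 pretraining epochs, 400 fine-tuning images (50 parents × an
8-spec mini plan) with 5 epochs, 200 held-out phantoms.

## Evaluation

The model's score is the probability of a frontal image (PFI); frontal is
the positive class throughout. The operating cutoff scans 0→1 in 0.001
steps; at cutoff c an image is called frontal iff PFI ≥ c, and
J(c) = sensitivity + specificity − 1. When a range of cutoffs attains the
maximum J, the **higher end** is chosen. The grid maximum never exceeds the
exact maximum over all distinct scores and equals it whenever scores lie on
the grid (property-tested against an exhaustive oracle).

Accuracy is the proportion correctly classified, from the 2×2 confusion
table. Confidence intervals are exact Clopper-Pearson (beta quantiles;
k = n gives lower bound (α/2)^(1/n) — for 1377/1377 at 95% that is 99.73%).
Model groups are compared by pooling per-model correct/incorrect counts
into a 2×2 table and applying Pearson's chi-square with df = 1 and **no**
continuity correction (samples are large; the correction is switchable). A
table with a zero outcome margin (e.g. both groups 100% correct) is defined
as homogeneous: χ² = 0, p = 1.

Robustness probes mirror common failure modes: a burned-in high-intensity
text block in a corner, rotation, zeroing one half of the image, and
center-crop-then-resquash; outputs keep the input shape so they feed
straight back into prediction.

## Numerical and design notes

* Rounding is numpy's round-half-even everywhere quantization occurs.
* The ±2° rotation round-trip is within ±1 grey level on interior pixels of
  smooth (band-limited) images; step edges can deviate more, which is a
  property of bilinear interpolation, not a defect.
* `youden_cutoff` detects ties by exact float equality; this is sound
  because equal sensitivity/specificity counts produce identical floats.
* Degenerate inputs are errors, not silent defaults: empty images,
  single-class prediction sets, zero-total chi-square groups, k > n.
* Seeds: every stochastic component takes an explicit seed; derived seeds
  are CRC32-based and stay below 2³¹.

## Limitations

Headline accuracies from ImageNet-scale pretraining on real radiographs
(99.7%+ on hundreds of test images) are out of reach at desk scale and are
not claimed; the package demonstrates the pipeline's arithmetic and
statistical claims exactly, and the transfer/augmentation effects
directionally, on phantoms. The CNN is deliberately small; it is not an
inception-style architecture, and throughput is not a goal.
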