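# Methods

## Problem

Nests of melanocytes (nevus cells) are compact clusters of dozens to
hundreds of cells near the dermal–epidermal junction in H&E-stained skin
sections. Segmenting them pixelwise in whole-slide-image (WSI) crops is a
binary segmentation task with a characteristic constraint: expert-labeled
ground truth is scarce relative to the volume of unlabeled tissue imagery.
`nestseg` implements a semi-supervised convolutional-autoencoder (CAE)
approach built for exactly that regime, together with a synthetic H&E-like
data generator that makes the whole pipeline testable end to end without
access to clinical data.

## Model

The network is a fixed convolutional autoencoder over 128×128×3 RGB
patches. All convolutions are 3×3 with size-preserving ("same") zero
padding; downsampling is 2×2 max-pooling; upsampling is 2×2
nearest-neighbour repetition. The hidden conv channel progression is

    encoder: 32, 64 |pool| 64, 128 |pool| 128, 64 |pool|   -> code 16×16×64
    decoder: 64, 32, 32, 64 |up| 64, 128 |up| 128, 64 |up| 64, 32 -> head

Two heads share everything else:

* **reconstruction**: final 3×3 conv, 3 channels, ReLU, trained with MSE
  (823,107 parameters in total);
* **segmentation**: final 3×3 conv, 1 channel, sigmoid, trained with binary
  cross-entropy (822,529 parameters; encoder 351,552, decoder 470,977).

The *encoder* is defined as everything through the third max-pool — the
layers that produce the 16×16×64 latent code. This boundary is what
"freeze the encoder" and "transfer the encoder" mean throughout. A
consequence worth keeping in mind when reading results: all spatial detail
passes through a 16×16 grid, so predicted masks have an effective
resolution of ~8-pixel blocks and DSC saturates below 1.0 even for a
perfectly trained model on crisp synthetic shapes.

On the padding width: size preservation with a 3×3 kernel forces a 1-pixel
border, which is what the implementation uses; every hidden activation then
keeps its 128/64/32/16-pixel spatial size, matching the layer table the
architecture is checked against.

## Training protocol

1. **Reconstruction (unsupervised)** — the reconstruction variant is
   trained on patches from *all* images, labeled and unlabeled; each input
   is its own target (MSE). No masks are needed.
2. **Frozen-encoder segmentation** — the encoder weights are copied
   bit-for-bit into a fresh segmentation variant, the decoder is
   re-initialised, the encoder is frozen, and training proceeds with BCE on
   labeled patches only. Because the encoder is fixed, the implementation
   precomputes each patch's latent code once and trains the decoder on
   codes; this is numerically identical to running the full forward pass
   every step and saves roughly a third of the phase's cost.
3. **Fine-tuning** — the encoder is unfrozen and the whole network trains
   end to end at a halved base learning rate.

Each phase checkpoints at the smallest validation loss (ties go to the
earlier epoch) and hands its best state to the next phase.

Optimisation is Adam (β₁=0.9, β₂=0.999, conventional defaults) with the
per-epoch learning-rate decay

    lr(e) = max(floor, −log10(0.01·e + 0.1) · base),

base = 1e-3 for phases 1–2 and 5e-4 for phase 3, floor = 1e-6. Note the
sign: the raw expression log10(0.01e+0.1)·base is negative for e < 90; the
negated form is the only reading that yields a positive, decaying rate
(1e-3 at epoch 0, floor from epoch 90 on), and that is what is implemented.

Weights are Glorot-uniform initialised (bound √(6/(fan_in+fan_out)) with
fan_in = 9·c_in, fan_out = 9·c_out); biases start at zero. A single seed
drives initialisation, decoder resets, and epoch shuffling, so identical
seeds reproduce loss histories and final weights bit for bit.

## Compute engine

No deep-learning framework is used: layers, backpropagation and Adam are
implemented directly on NumPy. Convolutions run as im2col + float32 BLAS
GEMM, chunked along the batch axis; max-pool backward routes gradients to
the exact first-wins argmax of each window; all large intermediates come
from a persistent buffer pool, which keeps the training loop GEMM-bound
(repeated multi-megabyte allocations are otherwise dominated by page-fault
cost). Backward passes are verified against central finite differences in
the test suite. When the encoder is frozen, backpropagation stops at the
encoder boundary.

## Data preparation

Splitting happens **before** patching, always at the image level, so no
pixels from a validation or test image can leak into training patches.
Splits are stratified by the labeled flag: labeled and unlabeled images are
apportioned independently with largest-remainder rounding (a 70-image,
39-labeled corpus at fractions 0.70/0.143/0.157 lands at 49/10/11 images
overall and 27/6/6 labeled).

Patch extraction scans a coarse grid with a 128-px stride (no overlap on
background). Whenever a grid window's mask tile contains at least one nest
pixel (`positive_rule`, configurable), its 3×3 grid-cell neighbourhood is
re-scanned at a 64-px stride — 50% overlap, oversampling the positive
class. Images whose dimensions are not grid-multiples are reflect-padded on
the bottom/right so border tissue is kept. Positive patches are then
augmented with four rotations (45°, 90°, 135°, 180°): right angles are
exact pixel permutations; 45°/135° use bilinear interpolation with reflect
padding for the image and nearest-neighbour re-binarised rotation for the
mask. Together, overlap and rotation bring the positive:negative patch
ratio toward 1.

Whole-image inference tiles the image at a 128-px stride (reflect-padded,
non-overlapping by default), stitches the per-tile probability maps —
overlapping tiles contribute their mean, an option aimed at the
patch-border artifacts this family of models shows — crops the padding,
and thresholds at 0.5 (ties count as positive).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
tissue biology: an eosin-pink background (RGB mean (0.91, 0.77, 0.86))
with low-frequency multiplicative texture (Gaussian-smoothed noise, σ=16 px,
±5%) and i.i.d. pixel noise (σ=0.02); 2–4 nests per image (radius 22–36 px
at the default 256×384 size), each a cluster of 30–80 hematoxylin-purple
cell disks (radius 4–8 px, RGB mean (0.42, 0.28, 0.58), per-cell colour
jitter σ=0.04) placed uniformly inside the nest radius. Ground truth is
defined *constructively*: the morphological closing (disk structuring
element at the maximum cell radius) of the union of the nest's cell disks.
That makes the mask exact by construction and lets tests re-rasterize the
same seeded geometry independently.

What this does **not** model: scanner artifacts, stain variability between
laboratories, nuclei scattered outside nests, chromatin texture inside
nuclei, and the extreme foreground/background imbalance of real WSIs.
Passing tests on synthetic data therefore demonstrate that the pipeline's
machinery — patching, protocol, optimisation, inference, metrics — works
and that the network can learn colour/texture-defined clusters; they say
nothing about clinical performance.

## Desk-scale test conditions

The repository's end-to-end checks run the full protocol at a size chosen
for a single CPU: 14 synthetic 128×128 images (50% labeled, 1–3 nests of
radius 18–30 px), batch size 4, and epoch budgets of a few units per phase,
evaluated on the held-out test images over three seeds against a mean-DSC
bar of 0.7. Batch size and epochs scale *together* with the corpus so the
optimizer takes a comparable number of steps per phase as a full-size run
would; the published-scale defaults (batch 64, epochs 50/40/20) remain the
package defaults. Small protocol-contract tests (freezing, resets,
determinism) use two-image corpora and 1–2 epochs.

## Evaluation

Pixelwise confusion counts with "nest" as the positive class;
DSC = 2TP/(2TP+FP+FN) (equal by algebra to the set form 2|X∩Y|/(|X|+|Y|)),
sensitivity TP/(TP+FN), specificity TN/(TN+FP). Conventions for degenerate
cases: empty-vs-empty DSC is 1.0; SEN/SPE with a zero denominator return
1.0 with a warning. Corpus-level numbers are unweighted per-image means by
default; pooled-pixel aggregation is available behind a flag.

## Known limitations

* The 16×16 code bounds mask resolution (see above); thin or tiny nests
  (few cells) are systematically missed — consistent with this
  architecture family's reported behaviour on small nests.
* Non-right-angle rotation augmentation interpolates and reflects at patch
  borders; it is not a pixel permutation, so augmented masks are not exact
  rigid transforms of the originals.
* At desk scale the optimizer takes tens of steps per phase, so phase-3
  fine-tuning can transiently degrade the phase-2 optimum before
  re-converging; best-validation checkpointing bounds but does not
  eliminate the effect. Full-scale budgets do not share this regime.
* The engine is single-threaded NumPy; it is meant for correctness and
  desk-scale experiments, not for training on real WSI volumes.
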