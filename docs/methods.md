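# Methods

## The model

CSBNet classifies RGB images directly in the compressed domain. A learned
*measurement operator* — the CS-Block — replaces the sensing matrix of
classical compressed sensing: three 3×3 stride-2 convolutions
(3 → 64 → 64 → 64, padding 1) halve the 224×224 input to 28×28, and a 1×1
convolution projects to X measurement channels, where

    X = round_half_up(192 · SR),   SR ∈ (0, 1].

No nonlinearity separates these four convolutions, so the composite is a
single affine map `y = A x + b` of the flattened image — exactly the role
of a measurement matrix, but with `A` learned end-to-end. The element-count
ratio of the pre-upsample map to the input is (28·28·X)/(224·224·3) = X/192,
the *effective* sensing rate; because X is an integer it can differ from
the nominal SR by up to 1/384, and both are always reported. The package
verifies the affinity claim literally: on a 16×16 toy the block is
materialized column-by-column into an explicit `(M, N)` matrix and compared
against the convolutional forward pass.

A nearest-neighbour up-sampling stage (factor 2, parameter-free) enlarges
the 28×28 map to 56×56 so the downstream 7×7 kernel always has support;
classification never reconstructs the image.

The feature extractor is AlexNet-derived: conv 7×7 stride 4 with 48 filters
(padding 2), max-pool k3 s2, conv 5×5 → c2, max-pool, three 3×3 convs
→ c3 → c4 → 128, ReLU after every convolution, then an adaptive average
pool to 2×2 so the flattened classifier input is 128·2·2 = 512 at every
sensing rate. A channel-attention stage (SE by default; ECA and CBAM as
drop-ins) reweights the 128 conv5 channels. The classifier is
512 → 1024 → 2048 → K fully connected layers, each preceded by dropout 0.5.

Training minimises mean cross-entropy H(p, q) = −Σ p log q (natural log,
epsilon floor 1e-12 inside the log) with Adam (β = 0.9/0.999) at learning
rate 1e-4.

## Width reconstruction from parameter totals

The widths c2, c3, c4 of feature convolutions 2–4 are not fixed by the
architecture. They are recovered by exhaustive integer search
(`reconstruct_widths`) against a pair of published ledger totals for the
SR = 0.7, K = 4 model: 6,003,328 with the SE stage and 6,001,144 without.
The difference, 2,184 parameters, admits exactly one biased two-FC SE
configuration on a (C ∈ [8,512]) × (r ∈ {2,4,8,16,32}) grid — C = 128,
r = 16 — which pins conv5 at 128 channels. Searching (c2, c3, c4) ∈ [8,512]³
then yields five exact solutions to the no-SE total; the tie-break is L1
distance in channel space to AlexNet's (192, 384, 256), selecting
**(408, 344, 286)**, which reproduces both totals exactly and is the shipped
default. The float32 ledger size is 6,003,328 × 4 B / 2²⁰ = 22.90 MB.
Totals are affine in X with slope 65 (1×1 projection) + 49·48 = 2,417.

## Numerical engine

No deep-learning framework is used: layers (conv via im2col + BLAS matmul,
max/adaptive pooling, nearest up-sampling, dropout, FC), the three attention
stages, softmax cross-entropy and Adam are implemented in numpy with
explicit backward passes, in float32. Attention backward passes are checked
against central finite differences. Initialization is uniform with variance
2/fan_in (He) for ReLU-followed layers and 1/fan_in for the purely affine
CS-Block; bias variance 0.5/fan_in. Variance preservation matters here
because the network has no normalization layers: a smaller init attenuates
activations multiplicatively over the ten-conv stack and stalls learning in
short runs.

One master seed derives independent sub-seeds (via `SeedSequence`) for data
generation, weight init, shuffling, dropout and augmentation, so a run is
bit-reproducible on fixed hardware/threading.

Degenerate inputs: normalization rejects x_max ≤ x_min; a precision/recall/
F1 denominator of zero (a class never predicted, common at SR = 0.05)
yields 0 with a warning; non-finite training loss aborts with a diagnostic;
adaptive pooling handles feature maps smaller than 2×2 by bin duplication.

## Preprocessing

Normalization is the affine map 2(x − x_min)/(x_max − x_min) − 1 onto
[−1, 1] with (x_min, x_max) = (0, 255) fixed by the 8-bit encoding (not per
image, which would alias brightness augmentation); a [0, 1] variant exists
for ablation. Augmentation is online and seeded: horizontal and vertical
flips each with probability 0.5 and a brightness factor drawn from
{0.7, 1.0, 1.3}, applied in raw-intensity space and clipped. Folder loading
follows the class-per-subdirectory convention with bilinear resize to
224×224.

## Synthetic data

The generator renders green elliptical leaves with vein texture on a
neutral background and class-specific lesions: small gray rectangles, long
tan streaks, dense orange pustules, or none (healthy). Per-image seeds are
derived from the dataset seed; a JSON manifest records file, class, seed
and lesion count per image. The classes are separable by coarse colour
statistics *by construction* (a logistic regression on mean channel values
separates rust from healthy at >0.95), which is what makes the desk-scale
learnability check meaningful. What the generator does **not** emulate:
natural background clutter, illumination fields, leaf pose/scale diversity,
camera noise, and intra-class disease-stage variation. Passing tests on
this data therefore demonstrate that the pipeline can extract and use
compressed-domain class signal, not that it reaches any particular accuracy
on real leaf photographs.

`lesion_contrast` (default 1.0) scales lesion blend strength and is the
difficulty dial: at 1.0 the task is easy enough that every sensing rate on
the grid reaches perfect held-out accuracy once converged.

## Desk-scale experiment sizes

Sizes were chosen so every check runs quickly on one CPU:

* **Learnability**: SR = 0.5, 5 epochs, batch 8, 200 training + 40
  validation images at default contrast. Hard criterion: beat chance
  (0.25); typical runs reach 0.7–1.0 (the headline claim of the method at
  desk scale is learnability, not a benchmark number).
* **SR sweep**: SRs (0.05, 0.3, 0.7), 6 epochs each, 200 + 40 images at
  `lesion_contrast = 0.55`. The reduced contrast gives the sweep dynamic
  range — at default contrast all rates saturate, and with very faint
  lesions (0.3) nothing learns in six epochs; at 0.55 accuracy rises with
  SR (observed (0.50, 0.50, 0.60), Spearman +0.87). Six epochs rather than
  three because three leaves all networks in the noise regime where the
  sweep measures initialization luck, not capacity. The test asserts only a
  non-negative rank correlation: a soft, scale-appropriate analogue of the
  positive SR–accuracy relationship.

## Known limitations

* Pure-numpy training is ~0.5 s per batch of 8 at 224×224 on one core;
  the package is for method study at desk scale, not GPU-scale benchmarks.
* The CS-Block's affinity means its four layers could in principle collapse
  to one convolution; they are kept separate to preserve the learned
  low-rank factorization structure and the published layer inventory.
* Only 224×224×3 inputs are supported; all shape arithmetic assumes it.
* Comparison backbones (plain AlexNet, ResNet-50 variants) are not
  implemented; their published parameter counts serve as documentation
  only.
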