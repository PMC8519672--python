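# Methods

This note documents the models, numerical choices and limitations of the
package; the README gives the high-level picture.

## Data model and preprocessing

Arrays are `(depth, height, width)` with axial slices along axis 0. NIfTI
files store `(x, y, z)`; the reader transposes to `(z, y, x)` and the
writer inverts it, so round trips are exact (bit-exact for integer masks).
DICOM series are ordered by the projection of each slice's
ImagePositionPatient onto the normal of ImageOrientationPatient; filename
order is never trusted, and a missing-position fallback to InstanceNumber
is logged. Rescale slope/intercept are applied on read.

Intensities are windowed by clipping to `[hu_min, hu_max]` and mapping
linearly to [0, 1]. The default window [−200, 250] HU is a conventional
liver window; it is configurable because preprocessing choices of published
pipelines vary and are often unstated. No resampling to isotropic spacing
is performed, and in-plane size is taken as-is (inputs whose size is not a
multiple of 16 are zero-padded for the forward pass and cropped back).

2.5D triplets: one per slice, channels (z−1, z, z+1), with edge replication
at the volume boundary so that every slice — including the first and last —
receives a prediction. The middle channel of triplet z is exactly slice z.

## Generator

Encoder: five stages at channel widths (32, 64, 128, 256, 256); each stage
is two convolution blocks and a residual addition of the stage input
(projected by 1×1×1 when widths differ). Stages are separated by 1×3×3
stride-(1,2,2) convolutions, so only the in-plane resolution is halved —
the through-plane extent of the feature volume is the 3-slice stack and is
preserved end to end.

Convolution blocks come in two modes. `series` (default) is a 1×3×3
convolution followed by a 3×1×1 convolution, each with batch normalization
and ReLU: a separable factorization that extracts in-plane and
through-plane structure with ~9/27 + 3/27 of the parameters of a full 3-d
kernel. `full3d` uses a single 3×3×3 convolution per block; in that mode
layer parameter counts equal the classical closed form `Cin·27·Cout + Cout`
(e.g. 128→128: 442 496; transposed 256→512: 3 539 456), which is useful for
cross-checking against published layer tables.

Batch normalization layers carry no learnable affine pair. Every norm here
is immediately followed by a biased convolution or linear layer, so a
learnable scale/shift would be redundant reparameterization; this also
keeps block parameter counts exactly equal to the convolutional closed
form. Running moments are tracked for evaluation mode.

Skip pathway: encoder features pass through a chained-residual-pooling
block before fusion. Each CRP block applies `crp_blocks` (default 2)
chained units of [max-pool 1×5×5, stride 1, padding 2 → 1×3×3 convolution →
norm → ReLU → dropout], each unit's output added residually to the running
sum. Pooling at stride 1 preserves shape while widening the receptive
field. With conv weights zeroed the block is exactly the identity — a
property the tests pin down. Dropout (rate 0.2 by default) lives inside
the CRP units.

Decoder: four stages. Features are upsampled by a transposed 1×3×3
convolution at stride (1,2,2) (output padding completes the exact
doubling), concatenated with the CRP-refined skip — concatenation rather
than addition, so a stage at width c consumes 2c channels — and processed
by two convolution blocks with a residual, mirroring the encoder. A final
1×1×1 convolution projects to the output channels; the center slice of the
depth axis is taken and passed through a sigmoid (softmax for a 2-channel
head, in which case foreground + background probabilities sum to 1).

## Critic

The Wasserstein critic scores the channel-wise fusion of (predicted mask,
annotation). Four convolution blocks at widths (64, 64, 32, 32) — note the
narrowing plan — each a 1×3×3 convolution with norm and leaky ReLU closed
by a 1×2×2 stride-2 max pool, then global average pooling and two fully
connected layers ending in a single linear unit. There is deliberately no
sigmoid anywhere on the output path: the Wasserstein objective needs an
unbounded score, and the classification-style 1/0 reading of the
adversarial game is treated as schematic. Inputs below the 16-pixel
receptive minimum are rejected. The critic sees mask pairs only; an
optional third channel with the CT slice is not enabled by default.

## Losses

* **Soft Dice**: `1 − 2Σpt/(Σp + Σt)`. The smoothing constant (1e−6) is
  applied only when both regions are empty, so the exact identities
  (0 for identical nonempty masks, 1 for disjoint) hold without smoothing.
* **Signed distance map**: boundary pixels are foreground pixels with an
  orthogonally adjacent background pixel (off-grid neighbors do not count
  as background); the map is the Euclidean distance transform to that
  pixel set, negated inside the region, computed per 2-d slice (the
  network predicts one center slice at a time). Uniform masks have no
  boundary and are rejected. An exhaustive nearest-boundary search serves
  as the test oracle on small grids.
* **Boundary loss**: mean over the domain of `φ·s`. Mean rather than sum
  keeps the α balance independent of image size; this normalization is a
  package decision, and `sum` is available via configuration.
* **Composite**: `α·Dice + (1−α)·boundary`, α = 0.1 by default. An
  optional linear schedule from α = 1 (Dice-dominant) down to the
  configured α exists for experiments where boundary emphasis should grow
  over training; it is off by default because the static weighting is the
  canonical objective.
* **Wasserstein**: critic minimizes `mean(fake) − mean(real)`; generator's
  adversarial term is `−mean(fake)`, weighted by λ (default 0.01, so the
  segmentation loss dominates; how the composite and adversarial signals
  combine is a free choice and is exposed as `loss.adv_weight`).

During training, slices whose mask is uniform (no boundary) use a level
set of +1 everywhere (empty mask) or −1 (full mask): the boundary term then
still pushes probabilities toward the correct constant, and the Dice term
on an empty target supplies no gradient on its own.

## Training loop

Per generator step: `n_critic` critic updates (each followed by clipping
all critic weights to ±`clip_c`), then one generator update on the
composite-plus-adversarial total. Real critic inputs fuse the annotation
with itself; fake inputs fuse the (detached) prediction with the
annotation. RMSProp for both players. Defaults n_critic = 5,
clip_c = 0.01, learning rates 5e−5 follow the original WGAN recipe and are
defaults, not reproductions of any published schedule. Batches are drawn
uniformly with replacement across all slice triplets. Every source of
randomness — initialization, dropout, batch order — derives from the
single config seed, so identical configs reproduce identical histories.
Non-finite inputs are rejected up front, and a non-finite loss aborts with
a diagnostic naming the offending term. The history logs every loss
component per step; the generator total is recomputable from the logged
parts at every step.

Inference (`predict_volume`) runs the generator in evaluation mode over all
triplets of a volume, thresholds the center-slice probabilities (default
0.5, strict inequality), and reassembles a mask volume of the input shape.

## Synthetic phantoms

A phantom is a randomly oriented ellipsoid with semi-axes drawn from
`radius_range` (fractions of each axis extent), its radius modulated by a
low-frequency angular sinusoid of amplitude `deform_amplitude` (relative
amplitude capped at 0.5 so the region stays star-shaped, hence connected;
the largest connected component is kept after rasterization). Intensities
default to fg 100 / bg −50 HU with Gaussian noise (σ = 15) — values chosen
to sit inside the default liver window with contrast and noise of the
order seen in windowed abdominal CT. Output is a pure function of the
spec; per-case seeds in datasets are derived by splitmix64 mixing of
(spec seed, case index), so cases are independent yet reproducible.

What the phantoms do not emulate: tumors and vessels, multi-organ
anatomy, partial-volume and beam-hardening effects, anisotropic spacing
artifacts, inter-patient variability. Tests passing on phantoms therefore
establish the correctness of the machinery (losses, gradients, loop
bookkeeping, I/O) — not clinical segmentation quality on real CT.

## Problem sizes used in verification

The verification suite and the acceptance script exercise the full loop as
a seeded overfitting run: 8 slice triplets from one (8, 32, 32) phantom, a
narrow generator (stage widths 8, 16, 32, 64, 64), n_critic = 1, batch 4,
200 steps, generator RMSProp at 5e−3 (a deliberately fast rate for a small
overfitting demonstration), λ = 0 so the segmentation objective is
isolated while the critic still trains and its clipping invariant is
checked after every update. Training-set Dice ≥ 0.90 at this scale
demonstrates that the composite loss and its gradients, the adversarial
bookkeeping, and the prediction path are correct end to end. Full-width
training on LiTS/CHAOS-scale data is operational through the same config
surface but is outside the scope of the test suite.

## Known limitations

* The layer stack is a minimal numpy autodiff implementation: correct (all
  kernels are verified against numerical gradients) but CPU-bound and not
  suited to full-resolution training.
* Plain weight clipping is the only Lipschitz mechanism (no gradient
  penalty or spectral norm).
* MRI intensity handling is generic min–max windowing only; no
  modality-specific normalization.
* The decoder wiring beyond the four mirrored stages (e.g. additional
  refinement layers some descriptions imply) is not reconstructible from
  available information and is not implemented; the four-stage mirror is
  the canonical VNet reading.
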