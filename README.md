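# liverseg

2.5D adversarial liver segmentation for CT volumes: a VNet-style generator
over axial slice triplets, chained-residual-pooling (CRP) skip connections,
a composite Dice + boundary loss, and a Wasserstein-GAN critic.

## Who this is for

Researchers and engineers working on abdominal CT segmentation who want a
small, fully inspectable implementation of boundary-aware adversarial
segmentation — every component, including the reverse-mode autodiff layer
stack it trains with, is plain numpy/scipy code in this repository, testable
without GPUs or external datasets.

## The method

**Input.** Each axial slice *z* is presented as a 2.5D triplet — the stack
of slices (*z*−1, *z*, *z*+1) — and the network predicts the foreground
probability map s_θ(p) of the center slice. Volumes come from NIfTI files
(LiTS-style `volume-*.nii` / `segmentation-*.nii` naming) or DICOM series
directories, windowed to a liver HU range and scaled to [0, 1].

**Generator.** A VNet-style encoder–decoder: five encoder stages with
channel plan (32, 64, 128, 256, 256), each stage two convolution blocks
plus a residual addition; strided-convolution downsampling (in-plane only);
four decoder stages with transposed-convolution upsampling. Convolutions
are factorized in series — an in-plane 1×3×3 followed by a through-plane
3×1×1 — to capture intra- and inter-slice information at a fraction of the
cost of full 3×3×3 kernels (a `full3d` mode with single 3×3×3 kernels is
also provided). Skip connections pass through chained residual pooling:
repeated size-preserving pool(1×5×5, stride 1)→conv units summed residually,
which enlarges the receptive field on the skip pathway before the features
are fused into the decoder by concatenation.

**Loss.** The generator minimizes

    L = α·L_Dice + (1 − α)·L_BD + λ·L_adv,      α = 0.1 by default

where L_Dice = 1 − 2|A∩B|/(|A|+|B|) is the soft Dice loss,
L_BD = mean_Ω φ_G(p)·s_θ(p) is the boundary loss — φ_G is the signed
Euclidean distance to the boundary ∂G of the ground-truth region G,
negative inside — and L_adv = −E[D(fake)] is the Wasserstein adversarial
term. The Dice term controls region overlap; the boundary term charges
probability mass in proportion to its distance from the true boundary,
which Dice alone cannot see.

**Critic.** A Wasserstein critic D scores the channel-fused pair
(prediction, annotation) with one unbounded scalar; it is trained on
E[D(fake)] − E[D(real)] with weight clipping to ±c after every update.

**Evaluation.** Accuracy (TP+TN)/total and Dice 2TP/(2TP+FP+FN), per volume
and pooled over summed confusion counts.

A synthetic phantom module generates deformed-ellipsoid "livers" in noisy
CT-like volumes with paired masks, so the entire pipeline is exercisable
with no external data.

## Worked example

`examples/04_train_and_evaluate.py` trains a narrow generator/critic pair
for 60 steps on the 8 slice triplets of one synthetic phantom and prints:

```
step   0: total +2.1193 (dice 0.9466, boundary +2.2496, adv -0.0023)
step  15: total -0.0513 (dice 0.1155, boundary -0.0698, adv -0.0021)
step  30: total -0.0652 (dice 0.0530, boundary -0.0783, adv -0.0023)
step  45: total -0.0635 (dice 0.0143, boundary -0.0721, adv -0.0030)
training-set accuracy 0.9991, Dice 0.9956
```

The Dice part falls toward 0 while the boundary part goes negative — the
network's probability mass settles inside the true region, where the level
set φ_G is negative. Training-set Dice near 1 shows that losses, gradients,
critic updates and weight clipping are all wired correctly; it is an
overfitting demonstration, not a claim about generalization. The other
example scripts cover phantom generation and I/O, the loss definitions on a
worked 1×5 example, and architecture introspection.

## Command line

```bash
liverseg make-phantoms --n 4 --shape 16,64,64 --seed 0 --out data/
liverseg train --config configs/default.yaml --data data/ --out run/
liverseg predict --model run/checkpoint.npz --volume data/volume-0.nii --out pred.nii
liverseg evaluate --pred preds/ --truth data/
```

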