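"""The WGAN optimization loop.

Each generator step consists of ``n_critic`` critic updates — Wasserstein
loss, RMSProp step, then weight clipping — followed by one generator update
minimizing ``α·L_Dice + (1−α)·L_BD + λ·L_adv``.  The critic's "real" input
is the annotation fused with itself; the "fake" input is the generator's
probability map (detached during critic updates) fused with the annotation.

Signed distance maps are precomputed once per training sample.  For slices
whose mask is uniform (no boundary exists) the level set is defined as +1
everywhere when the mask is empty and −1 when it is full, so the boundary
term still pushes probabilities in the right direction.

Everything is driven by a single seed: parameter init, dropout masks and
batch sampling are all derived from ``TrainConfig.seed``, so identical
configurations reproduce identical histories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import losses, metrics, nn
from .data_io import CTVolume, make_triplets
from .discriminator import Critic, CriticSpec, build_discriminator, clip_weights, fuse_inputs
from .generator import ArchSpec, VNetGenerator, build_generator
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainResult",
    "train",
    "predict_volume",
    "triplet_dataset",
    "dataset_dice",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The WGAN bookkeeping defaults (n_critic=5, clip_c=0.01, RMSProp at
    5e−5) follow the original Wasserstein-GAN recipe; they are defaults,
    not reproductions of any published schedule.
    """

    arch: ArchSpec = field(default_factory=ArchSpec)
    critic: CriticSpec = field(default_factory=CriticSpec)
    loss: losses.LossConfig = field(default_factory=losses.LossConfig)
    n_critic: int = 5
    clip_c: float = 0.01
    lr_generator: float = 5e-5
    lr_critic: float = 5e-5
    batch_size: int = 4
    max_steps: int = 100
    seed: int = 0
    alpha_schedule: bool = False

    def __post_init__(self):
        if self.n_critic < 1:
            raise ValueError(f"n_critic must be >= 1, got {self.n_critic}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.lr_generator <= 0 or self.lr_critic <= 0:
            raise ValueError("learning rates must be positive")
        if self.clip_c <= 0:
            raise ValueError(f"clip_c must be positive, got {self.clip_c}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")


@dataclass
class TrainHistory:
    """Per-step loss records: one per generator step, n_critic per critic."""

    generator_records: list = field(default_factory=list)
    critic_records: list = field(default_factory=list)


@dataclass
class TrainResult:
    generator: VNetGenerator
    critic: Critic
    history: TrainHistory


def _phi_for(mask: np.ndarray) -> np.ndarray:
    fg = int(mask.sum())
    if fg == 0:
        return np.ones_like(mask, dtype=float)
    if fg == mask.size:
        return -np.ones_like(mask, dtype=float)
    return losses.signed_distance_map(mask)


def _check_finite(value: float, term: str, step: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite {term} loss ({value}) at generator step {step}; aborting"
        )


def _alpha_at(cfg: TrainConfig, step: int) -> float:
    """Static α by default; optional linear Dice-dominant -> boundary-dominant."""
    if not cfg.alpha_schedule:
        return cfg.loss.alpha
    frac = step / max(cfg.max_steps - 1, 1)
    return 1.0 + (cfg.loss.alpha - 1.0) * frac


def train(config: TrainConfig, dataset) -> TrainResult:
    """Run the adversarial loop on ``dataset`` of (triplet, center-mask) pairs.

    ``dataset``: sequence of ``(stack, mask)`` with ``stack`` shaped
    (3, H, W) (windowed intensities) and ``mask`` (H, W) binary.
    """
    data = [(np.asarray(s, dtype=float), np.asarray(m)) for s, m in dataset]
    if not data:
        raise ValueError("dataset must be nonempty")
    for i, (stack, mask) in enumerate(data):
        if not np.isfinite(stack).all():
            raise ValueError(f"dataset sample {i}: non-finite intensities")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError(f"dataset sample {i}: mask must be binary {{0,1}}")
    phis = [_phi_for(m) for _, m in data]
    n_samples = len(data)

    rng = np.random.default_rng(config.seed)
    generator = build_generator(config.arch, seed=config.seed)
    critic = build_discriminator(config.critic, seed=config.seed + 1)
    opt_g = nn.RMSProp(generator.parameters(), lr=config.lr_generator)
    opt_c = nn.RMSProp(critic.parameters(), lr=config.lr_critic)
    history = TrainHistory()

    lam = config.loss.adv_weight

    def batch(indices):
        stacks = np.stack([data[i][0] for i in indices])
        masks = np.stack([data[i][1] for i in indices]).astype(float)
        phi = np.stack([phis[i] for i in indices])
        return stacks, masks, phi

    generator.train()
    critic.train()
    for step in range(config.max_steps):
        # ----------------------------------------------------- critic updates
        for substep in range(config.n_critic):
            idx = rng.integers(0, n_samples, size=config.batch_size)
            stacks, masks, _ = batch(idx)
            pred = generator(Tensor(stacks)).detach()
            real_scores = critic(fuse_inputs(Tensor(masks), Tensor(masks)))
            fake_scores = critic(fuse_inputs(pred.reshape(pred.shape[0],
                                                          *pred.shape[2:]),
                                             Tensor(masks)))
            loss_c = losses.critic_loss(real_scores, fake_scores)
            _check_finite(loss_c.item(), "critic", step)
            opt_c.zero_grad()
            loss_c.backward()
            opt_c.step()
            clip_weights(critic, config.clip_c)
            history.critic_records.append(
                {"step": step, "substep": substep, "loss": loss_c.item()}
            )

        # -------------------------------------------------- generator update
        alpha = _alpha_at(config, step)
        idx = rng.integers(0, n_samples, size=config.batch_size)
        stacks, masks, phi = batch(idx)
        pred = generator(Tensor(stacks))
        flat = pred.reshape(pred.shape[0], *pred.shape[2:])
        dice_part = losses.dice_loss(flat, masks)
        bnd_part = losses.boundary_loss(flat, phi, reduction=config.loss.reduction)
        if lam > 0:
            fake_scores = critic(fuse_inputs(flat, Tensor(masks)))
            adv_part = losses.generator_adv_loss(fake_scores)
        else:
            adv_part = Tensor(0.0)
        total = alpha * dice_part + (1.0 - alpha) * bnd_part + lam * adv_part
        for term, value in (("dice", dice_part.item()),
                            ("boundary", bnd_part.item()),
                            ("adversarial", adv_part.item()),
                            ("total", total.item())):
            _check_finite(value, term, step)
        opt_g.zero_grad()
        critic.zero_grad()  # adversarial gradients flow through the critic
        total.backward()
        critic.zero_grad()  # ...but never update it here
        opt_g.step()
        history.generator_records.append({
            "step": step,
            "total": total.item(),
            "dice": dice_part.item(),
            "boundary": bnd_part.item(),
            "adv": adv_part.item(),
            "alpha": alpha,
        })
    generator.eval()
    critic.eval()
    return TrainResult(generator=generator, critic=critic, history=history)


# ------------------------------------------------------------------ datasets
def triplet_dataset(volume, mask) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pair each slice triplet of ``volume`` with its center-slice mask."""
    mask = np.asarray(mask)
    triplets = make_triplets(volume)
    return [(t.stack, mask[t.center_index]) for t in triplets]


def predict_volume(generator: VNetGenerator, vol, threshold: float = 0.5,
                   batch_size: int = 8) -> np.ndarray:
    """Segment a whole volume slice by slice.

    Builds the 2.5D triplets, forwards each through the generator in eval
    mode, thresholds the center-slice probabilities and reassembles a mask
    volume of the input's shape.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    voxels = vol.voxels if isinstance(vol, CTVolume) else np.asarray(vol)
    triplets = make_triplets(voxels)
    was_training = generator.training
    generator.eval()
    out = np.zeros(voxels.shape, dtype=np.uint8)
    try:
        for start in range(0, len(triplets), batch_size):
            chunk = triplets[start : start + batch_size]
            stacks = np.stack([t.stack for t in chunk])
            probs = generator(Tensor(stacks)).data[:, 0]
            for t, p in zip(chunk, probs):
                out[t.center_index] = (p > threshold).astype(np.uint8)
    finally:
        generator.train(was_training)
    return out


def dataset_dice(generator: VNetGenerator, dataset, threshold: float = 0.5) -> float:
    """Pooled Dice of thresholded predictions over a triplet dataset."""
    was_training = generator.training
    generator.eval()
    try:
        counts = metrics.ConfusionCounts(0, 0, 0, 0)
        for stack, mask in dataset:
            prob = generator(Tensor(np.asarray(stack)[None])).data[0, 0]
            pred = (prob > threshold).astype(np.uint8)
            counts = counts + metrics.confusion_counts(pred, np.asarray(mask))
    finally:
        generator.train(was_training)
    return metrics.dice_coefficient(counts)


# --------------------------------------------------------------- checkpoints
def save_checkpoint(path, generator: VNetGenerator, critic: Critic | None = None) -> None:
    """Persist model weights plus their architecture specs (npz container)."""
    payload = {f"generator::{k}": v for k, v in generator.state_dict().items()}
    meta = {"arch": asdict(generator.spec)}
    if critic is not None:
        payload.update({f"critic::{k}": v for k, v in critic.state_dict().items()})
        meta["critic"] = asdict(critic.spec)
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **payload)


def load_checkpoint(path) -> tuple[VNetGenerator, Critic | None]:
    """Rebuild models from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(Path(path)) as archive:
        meta = json.loads(bytes(archive["meta"].tobytes()).decode())
        arch = meta["arch"]
        arch["stage_channels"] = tuple(arch["stage_channels"])
        generator = build_generator(ArchSpec(**arch))
        generator.load_state_dict({
            k.split("::", 1)[1]: archive[k]
            for k in archive.files if k.startswith("generator::")
        })
        generator.eval()
        critic = None
        if "critic" in meta:
            cspec = meta["critic"]
            cspec["block_channels"] = tuple(cspec["block_channels"])
            critic = build_discriminator(CriticSpec(**cspec))
            critic.load_state_dict({
                k.split("::", 1)[1]: archive[k]
                for k in archive.files if k.startswith("critic::")
            })
            critic.eval()
    return generator, critic
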