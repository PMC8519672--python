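"""The Wasserstein critic that scores (predicted mask, annotation) pairs.

The critic sees the two masks fused as channels, passes them through four
convolution blocks (channel plan 64, 64, 32, 32; 1x3x3 kernels, each block
closed by a 1x2x2 max pooling), global-average-pools, and finishes with two
fully connected layers ending in a single *linear* unit.  There is no
sigmoid or softmax anywhere on the output path: a Wasserstein critic must
emit an unbounded real score, and its Lipschitz constraint is enforced by
clipping every weight to [−c, c] after each update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = ["CriticSpec", "fuse_inputs", "build_discriminator", "Critic", "clip_weights"]


@dataclass(frozen=True)
class CriticSpec:
    """Critic architecture hyperparameters."""

    block_channels: tuple[int, ...] = (64, 64, 32, 32)
    fc_units: int = 32
    in_channels: int = 2
    leaky_slope: float = 0.2

    def __post_init__(self):
        if len(self.block_channels) < 1:
            raise ValueError("need at least one convolution block")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")

    @property
    def min_size(self) -> int:
        """Smallest in-plane extent the pooling pyramid supports."""
        return 2 ** len(self.block_channels)


def fuse_inputs(pred_mask, annotation):
    """Channel-wise concatenation: channel 0 = prediction, channel 1 = truth.

    Accepts single maps ``(H, W)`` (returning ``(2, H, W)``) or batches
    ``(N, H, W)`` (returning ``(N, 2, H, W)``); works on arrays and
    autodiff tensors alike.
    """
    tensor_input = isinstance(pred_mask, Tensor) or isinstance(annotation, Tensor)
    p = nn.as_tensor(pred_mask)
    a = nn.as_tensor(annotation)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    if p.ndim == 2:
        h, w = p.shape
        fused = nn.concat([p.reshape(1, h, w), a.reshape(1, h, w)], axis=0)
    elif p.ndim == 3:
        n, h, w = p.shape
        fused = nn.concat(
            [p.reshape(n, 1, h, w), a.reshape(n, 1, h, w)], axis=1
        )
    else:
        raise ValueError(f"expected (H, W) or (N, H, W) maps, got shape {p.shape}")
    return fused if tensor_input else fused.data


class Critic(nn.Module):
    """Fused mask stack -> one unbounded scalar score per sample."""

    def __init__(self, spec: CriticSpec = CriticSpec(), seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        blocks = []
        cin = spec.in_channels
        for cout in spec.block_channels:
            blocks.append(nn.Sequential(
                nn.Conv3d(cin, cout, (1, 3, 3), padding=(0, 1, 1), rng=rng),
                nn.BatchNorm3d(cout),
                nn.LeakyReLU(spec.leaky_slope),
            ))
            cin = cout
        self.blocks = nn.ModuleList(blocks)
        self.fc1 = nn.Linear(cin, spec.fc_units, rng=rng)
        self.fc2 = nn.Linear(spec.fc_units, 1, rng=rng)

    def forward(self, x) -> Tensor:
        x = nn.as_tensor(x)
        if x.ndim == 3:  # single fused stack (C, H, W)
            x = x.reshape(1, *x.shape)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected (N, {self.spec.in_channels}, H, W) input, got {x.shape}"
            )
        n, c, h, w = x.shape
        if h < self.spec.min_size or w < self.spec.min_size:
            raise ValueError(
                f"input {h}x{w} smaller than the critic's receptive-field "
                f"minimum {self.spec.min_size}"
            )
        feat = x.reshape(n, c, 1, h, w)
        for block in self.blocks:
            feat = block(feat)
            feat = nn.maxpool3d(feat, (1, 2, 2), stride=(1, 2, 2))
        pooled = feat.mean(axis=(2, 3, 4))  # global average pool -> (N, C)
        hidden = self.fc1(pooled).leaky_relu(self.spec.leaky_slope)
        return self.fc2(hidden).reshape(n)


def build_discriminator(spec: CriticSpec = CriticSpec(), seed: int = 0) -> Critic:
    """Construct the WGAN critic from a :class:`CriticSpec`."""
    return Critic(spec, seed=seed)


def clip_weights(model: nn.Module, c: float) -> nn.Module:
    """Clamp every trainable scalar of ``model`` into [−c, c] in place."""
    if c <= 0:
        raise ValueError(f"clipping constant must be positive, got {c}")
    for p in model.parameters():
        np.clip(p.data, -c, c, out=p.data)
    return model
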