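"""The 2.5D VNet segmentation generator.

The network consumes a slice triplet (three adjacent axial slices) and
predicts a foreground probability map for the center slice.  Structure:

* five encoder stages with channel plan (32, 64, 128, 256, 256), each stage
  two convolution blocks plus a within-stage residual addition;
* strided-convolution downsampling (in-plane only — the through-plane
  extent is the 3-slice stack and is preserved);
* four decoder stages: transposed-convolution upsampling, skip features
  refined by chained-residual-pooling (CRP) blocks and fused by channel
  concatenation, then two convolution blocks with a residual;
* a final 1x1x1 projection over the center slice with a sigmoid (softmax
  when two output channels are configured).

Two kernel modes are available.  ``series`` (default) factorizes each 3-d
convolution into an in-plane 1x3x3 followed by a through-plane 3x1x1 —
cheap separable extraction of intra- and inter-slice information.
``full3d`` uses single 3x3x3 kernels; its per-layer parameter counts equal
the classical closed form ``Cin·27·Cout + Cout``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "ArchSpec",
    "series_conv_block",
    "crp_block",
    "downsample_block",
    "upsample_block",
    "build_generator",
    "VNetGenerator",
    "count_parameters",
]

count_parameters = nn.count_parameters


@dataclass(frozen=True)
class ArchSpec:
    """Generator architecture hyperparameters."""

    stage_channels: tuple[int, ...] = (32, 64, 128, 256, 256)
    kernel_mode: str = "series"
    crp_kernel: int = 5
    crp_blocks: int = 2
    dropout_rate: float = 0.2
    in_slices: int = 3
    out_channels: int = 1

    def __post_init__(self):
        if len(self.stage_channels) != 5:
            raise ValueError(
                f"expected 5 encoder stages, got {len(self.stage_channels)}"
            )
        if self.kernel_mode not in ("series", "full3d"):
            raise ValueError(f"unknown kernel_mode {self.kernel_mode!r}")
        if self.crp_kernel % 2 != 1:
            raise ValueError(f"crp_kernel must be odd, got {self.crp_kernel}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.in_slices != 3:
            raise ValueError("the 2.5D input unit is a 3-slice stack")
        if self.out_channels not in (1, 2):
            raise ValueError(f"out_channels must be 1 or 2, got {self.out_channels}")


def series_conv_block(cin: int, cout: int, mode: str = "series",
                      rng: np.random.Generator | None = None) -> nn.Module:
    """One convolution block: conv(s) + batch norm + ReLU, size preserving.

    ``series``: 1x3x3 then 3x1x1 kernels (each with norm + ReLU);
    ``full3d``: a single 3x3x3 kernel.
    """
    if cin < 1 or cout < 1:
        raise ValueError(f"channel counts must be >= 1, got {cin}->{cout}")
    rng = rng if rng is not None else np.random.default_rng(0)
    if mode == "series":
        return nn.Sequential(
            nn.Conv3d(cin, cout, (1, 3, 3), padding=(0, 1, 1), rng=rng),
            nn.BatchNorm3d(cout),
            nn.ReLU(),
            nn.Conv3d(cout, cout, (3, 1, 1), padding=(1, 0, 0), rng=rng),
            nn.BatchNorm3d(cout),
            nn.ReLU(),
        )
    if mode == "full3d":
        return nn.Sequential(
            nn.Conv3d(cin, cout, (3, 3, 3), padding=(1, 1, 1), rng=rng),
            nn.BatchNorm3d(cout),
            nn.ReLU(),
        )
    raise ValueError(f"unknown kernel mode {mode!r}")


def downsample_block(cin: int, cout: int,
                     rng: np.random.Generator | None = None) -> nn.Module:
    """Strided 1x3x3 convolution halving the in-plane resolution."""
    if cin < 1 or cout < 1:
        raise ValueError(f"channel counts must be >= 1, got {cin}->{cout}")
    rng = rng if rng is not None else np.random.default_rng(0)
    return nn.Sequential(
        nn.Conv3d(cin, cout, (1, 3, 3), stride=(1, 2, 2), padding=(0, 1, 1), rng=rng),
        nn.BatchNorm3d(cout),
        nn.ReLU(),
    )


def upsample_block(cin: int, cout: int, mode: str = "series",
                   rng: np.random.Generator | None = None) -> nn.Module:
    """Transposed convolution doubling the in-plane resolution."""
    if cin < 1 or cout < 1:
        raise ValueError(f"channel counts must be >= 1, got {cin}->{cout}")
    rng = rng if rng is not None else np.random.default_rng(0)
    kernel = (1, 3, 3) if mode == "series" else (3, 3, 3)
    pad = (0, 1, 1) if mode == "series" else (1, 1, 1)
    return nn.Sequential(
        nn.ConvTranspose3d(cin, cout, kernel, stride=(1, 2, 2), padding=pad,
                           output_padding=(0, 1, 1), rng=rng),
        nn.BatchNorm3d(cout),
        nn.ReLU(),
    )


class CRPBlock(nn.Module):
    """Chained residual pooling on a skip pathway.

    ``n_units`` chained units of [maxpool (1,k,k) stride 1 -> conv -> norm
    -> ReLU -> dropout], each added residually to the running sum.  Output
    shape and channel count equal the input's; with conv weights zeroed the
    block is the identity.
    """

    def __init__(self, channels: int, n_units: int = 2, pool_kernel: int = 5,
                 dropout_rate: float = 0.2, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        pad = pool_kernel // 2
        self.pool_kernel = pool_kernel
        self.pool_pad = pad
        self.units = nn.ModuleList(
            nn.Sequential(
                nn.Conv3d(channels, channels, (1, 3, 3), padding=(0, 1, 1), rng=rng),
                nn.BatchNorm3d(channels),
                nn.ReLU(),
                nn.Dropout(dropout_rate),
            )
            for _ in range(n_units)
        )

    def forward(self, x: Tensor) -> Tensor:
        out = x
        path = x
        for unit in self.units:
            path = nn.maxpool3d(path, (1, self.pool_kernel, self.pool_kernel),
                                stride=1, padding=(0, self.pool_pad, self.pool_pad))
            path = unit(path)
            out = out + path
        return out


def crp_block(channels: int, n_units: int = 2, pool_kernel: int = 5,
              dropout_rate: float = 0.2,
              rng: np.random.Generator | None = None) -> CRPBlock:
    return CRPBlock(channels, n_units, pool_kernel, dropout_rate, rng)


class _Stage(nn.Module):
    """Two convolution blocks with a within-stage residual addition."""

    def __init__(self, cin, cout, mode, rng):
        super().__init__()
        self.block1 = series_conv_block(cin, cout, mode, rng)
        self.block2 = series_conv_block(cout, cout, mode, rng)
        self.project = (nn.Conv3d(cin, cout, (1, 1, 1), rng=rng)
                        if cin != cout else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.block2(self.block1(x))
        shortcut = self.project(x) if self.project is not None else x
        return h + shortcut


class VNetGenerator(nn.Module):
    """Maps (N, 3, H, W) slice triplets to (N, out_channels, H, W) probabilities."""

    n_downsamples = 4

    def __init__(self, spec: ArchSpec = ArchSpec(), seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.stage_channels
        mode = spec.kernel_mode

        self.enc_stages = nn.ModuleList(
            _Stage(1 if i == 0 else ch[i - 1], ch[i], mode, rng) for i in range(5)
        )
        self.down = nn.ModuleList(
            downsample_block(ch[i], ch[i], rng) for i in range(4)
        )
        # decoder works from the deepest stage back up: skip stages 3,2,1,0
        self.up = nn.ModuleList(
            upsample_block(ch[4] if j == 3 else ch[j + 1], ch[j], mode, rng)
            for j in reversed(range(4))
        )
        self.crp = nn.ModuleList(
            crp_block(ch[j], spec.crp_blocks, spec.crp_kernel, spec.dropout_rate, rng)
            for j in reversed(range(4))
        )
        self.dec_stages = nn.ModuleList(
            _Stage(2 * ch[j], ch[j], mode, rng) for j in reversed(range(4))
        )
        self.head = nn.Conv3d(ch[0], spec.out_channels, (1, 1, 1), rng=rng)
        self._reseed_dropout(seed)

    def _reseed_dropout(self, seed: int) -> None:
        for i, module in enumerate(m for m in self.modules()
                                   if isinstance(m, nn.Dropout)):
            module.reseed(seed * 1000003 + i)

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected input (N, 3, H, W), got {x.shape}")
        n, _, h, w = x.shape
        factor = 2 ** self.n_downsamples
        ph = (-h) % factor
        pw = (-w) % factor
        volume = x.reshape(n, 1, 3, h, w)
        if ph or pw:
            logger.info("padding in-plane size (%d, %d) to a multiple of %d", h, w, factor)
            if pw:
                volume = nn.concat([volume, Tensor(np.zeros((n, 1, 3, h, pw)))], axis=4)
            if ph:
                volume = nn.concat(
                    [volume, Tensor(np.zeros((n, 1, 3, ph, w + pw)))], axis=3
                )

        skips = []
        feat = volume
        for i in range(4):
            feat = self.enc_stages[i](feat)
            skips.append(feat)
            feat = self.down[i](feat)
        feat = self.enc_stages[4](feat)

        for k in range(4):  # k=0 is the deepest decoder stage (skip index 3-k)
            feat = self.up[k](feat)
            refined = self.crp[k](skips[3 - k])
            feat = self.dec_stages[k](nn.concat([feat, refined], axis=1))

        logits = self.head(feat)  # (N, C, 3, H', W')
        center = logits[:, :, self.spec.in_slices // 2]  # (N, C, H', W')
        if self.spec.out_channels == 1:
            probs = center.sigmoid()
        else:
            shifted = center - Tensor(center.data.max(axis=1, keepdims=True))
            exp = shifted.exp()
            probs = exp / exp.sum(axis=1, keepdims=True)
        if ph or pw:
            probs = probs[:, :, :h, :w]
        return probs

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        """Channel widths read back from the built encoder stages."""
        widths = []
        for stage in self.enc_stages:
            conv = stage.block2.layers[0]
            widths.append(conv.weight.shape[0])
        return tuple(widths)


def build_generator(spec: ArchSpec = ArchSpec(), seed: int = 0) -> VNetGenerator:
    """Construct the 2.5D VNet generator from an :class:`ArchSpec`."""
    return VNetGenerator(spec, seed=seed)
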