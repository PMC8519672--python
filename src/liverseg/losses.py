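"""Training objectives: Dice loss, boundary loss via signed distance maps,
their weighted composite, and the Wasserstein critic/generator losses.

Every function accepts plain numpy arrays (returning floats) or autodiff
:class:`~liverseg.nn.Tensor` inputs (returning scalar tensors), so the same
definitions serve both evaluation and gradient-based training.

Definitions
-----------
Dice loss           ``1 − 2|A∩B| / (|A|+|B|)`` with the soft relaxation
                    ``|A∩B| = Σ p·t`` and ``|A|+|B| = Σ p + Σ t``.
Signed distance map Euclidean distance to the boundary pixels of the
                    ground-truth region G, negated inside G (a level set
                    that is zero exactly on ∂G).
Boundary loss       mean over the domain of ``φ_G(p) · s_θ(p)``: probability
                    mass far outside the true boundary is penalized in
                    proportion to its distance, mass inside is rewarded.
Composite loss      ``α·L_Dice + (1−α)·L_BD`` with α = 0.1 by default.
Wasserstein losses  critic minimizes ``mean(D(fake)) − mean(D(real))``;
                    the generator minimizes ``−mean(D(fake))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "dice_loss",
    "signed_distance_map",
    "boundary_loss",
    "composite_loss",
    "critic_loss",
    "generator_adv_loss",
]

_EPS = 1e-6


@dataclass(frozen=True)
class LossConfig:
    """Weights of the generator objective.

    alpha:      balance between Dice (α) and boundary (1−α) terms, in [0, 1].
    reduction:  'mean' or 'sum' over the image domain for the boundary term.
    adv_weight: λ ≥ 0 scaling of the adversarial term in the generator total.
    """

    alpha: float = 0.1
    reduction: str = "mean"
    adv_weight: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.reduction not in ("mean", "sum"):
            raise ValueError(f"reduction must be 'mean' or 'sum', got {self.reduction!r}")
        if self.adv_weight < 0:
            raise ValueError(f"adv_weight must be >= 0, got {self.adv_weight}")


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _check_shapes(a, b, op: str) -> None:
    sa, sb = _data(a).shape, _data(b).shape
    if sa != sb:
        raise ValueError(f"{op}: shape mismatch {sa} vs {sb}")


def dice_loss(pred, target):
    """Soft Dice loss in [0, 1]; 0 iff the prediction equals a nonempty target.

    The smoothing constant is applied only when both regions are empty, so
    the exact identities (0 for identical, 1 for disjoint) hold unsmoothed.
    """
    _check_shapes(pred, target, "dice_loss")
    t = _data(target)
    if isinstance(pred, Tensor):
        both_empty = pred.data.sum() == 0 and t.sum() == 0
        eps = _EPS if both_empty else 0.0
        inter = (pred * Tensor(t)).sum()
        denom = pred.sum() + float(t.sum())
        return 1.0 - (2.0 * inter + eps) / (denom + eps)
    p = _data(pred)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    if denom == 0.0:
        return 1.0 - (2.0 * inter + _EPS) / (denom + _EPS)
    return 1.0 - 2.0 * inter / denom


def signed_distance_map(target: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the boundary pixels of region G.

    Boundary pixels are foreground pixels with a 4-adjacent (orthogonal)
    background neighbor; they map to 0.  Values are negative strictly
    inside G and positive outside.  Raises on all-foreground or
    all-background masks, where the boundary is undefined.
    """
    m = np.asarray(target)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("signed_distance_map: mask must be binary {0,1}")
    m = m.astype(bool)
    total = m.size
    fg = int(m.sum())
    if fg == 0 or fg == total:
        raise ValueError(
            "signed_distance_map: mask is all-%s; boundary undefined"
            % ("foreground" if fg else "background")
        )
    structure = ndimage.generate_binary_structure(m.ndim, 1)  # orthogonal adjacency
    eroded = ndimage.binary_erosion(m, structure=structure, border_value=1)
    boundary = m & ~eroded
    dist = ndimage.distance_transform_edt(~boundary)
    phi = np.where(m, -dist, dist)
    return phi + 0.0  # normalize -0.0 on boundary pixels


def boundary_loss(pred, phi, reduction: str = "mean"):
    """Reduction over the domain of ``φ_G(p) · s_θ(p)``; may be negative."""
    _check_shapes(pred, phi, "boundary_loss")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    phi_arr = _data(phi)
    if isinstance(pred, Tensor):
        prod = pred * Tensor(phi_arr)
        return prod.mean() if reduction == "mean" else prod.sum()
    prod = _data(pred) * phi_arr
    return float(prod.mean() if reduction == "mean" else prod.sum())


def composite_loss(pred, target, cfg: LossConfig = LossConfig(), phi=None):
    """``α·L_Dice + (1−α)·L_BD``.

    ``phi`` may be precomputed (e.g. once per training sample); otherwise it
    is derived from ``target``.
    """
    if phi is None:
        phi = signed_distance_map(_data(target))
    d = dice_loss(pred, target)
    b = boundary_loss(pred, phi, reduction=cfg.reduction)
    return cfg.alpha * d + (1.0 - cfg.alpha) * b


def _score_mean(scores):
    if isinstance(scores, Tensor):
        if scores.size == 0:
            raise ValueError("empty score sequence")
        return scores.mean()
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score sequence")
    return float(arr.mean())


def critic_loss(real_scores, fake_scores):
    """``mean(fake) − mean(real)`` — what the Wasserstein critic minimizes.

    Its negation is the Wasserstein objective the critic maximizes.
    """
    return _score_mean(fake_scores) - _score_mean(real_scores)


def generator_adv_loss(fake_scores):
    """``−mean(fake)``: the generator raises the critic's score of its output."""
    return -_score_mean(fake_scores)
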