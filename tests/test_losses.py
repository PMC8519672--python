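"""Loss definitions checked against brute-force oracles and worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liverseg import nn
from liverseg.losses import (
    LossConfig,
    boundary_loss,
    composite_loss,
    critic_loss,
    dice_loss,
    generator_adv_loss,
    signed_distance_map,
)


# ------------------------------------------------------------------ Dice loss
def test_dice_loss_identity_disjoint_and_half_overlap():
    grid = np.zeros((4, 4))
    grid[:2, :2] = 1
    assert dice_loss(grid, grid) == 0.0
    other = np.zeros((4, 4))
    other[2:, 2:] = 1
    assert dice_loss(grid, other) == 1.0
    # |A| = |B| = 4 with |A ∩ B| = 2  ->  1 - 2·2/8 = 0.5
    shifted = np.zeros((4, 4))
    shifted[:2, 1:3] = 1
    assert dice_loss(grid, shifted) == 0.5


def test_dice_loss_both_empty_is_zero_and_mismatch_raises():
    empty = np.zeros((3, 3))
    assert dice_loss(empty, empty) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_soft_dice_matches_binary_dice_on_binary_probabilities(rng):
    mask = (rng.random((6, 6)) > 0.5).astype(float)
    target = (rng.random((6, 6)) > 0.5).astype(float)
    hard = dice_loss(mask, target)
    soft = dice_loss(nn.Tensor(mask, requires_grad=True), target)
    assert soft.item() == pytest.approx(hard)


# -------------------------------------------------------- signed distance map
def brute_force_sdm(mask):
    """Exhaustive nearest-boundary search: the independent oracle."""
    m = np.asarray(mask, dtype=bool)
    # boundary: foreground pixels with an in-bounds orthogonal background
    # neighbor (off-grid neighbors do not count as background)
    boundary = set()
    for idx in np.ndindex(m.shape):
        if not m[idx]:
            continue
        for axis in range(m.ndim):
            for step in (-1, 1):
                probe = list(idx)
                probe[axis] += step
                if 0 <= probe[axis] < m.shape[axis] and not m[tuple(probe)]:
                    boundary.add(idx)
    out = np.zeros(m.shape, dtype=float)
    for idx in np.ndindex(m.shape):
        d = min(
            np.sqrt(sum((a - b) ** 2 for a, b in zip(idx, bidx)))
            for bidx in boundary
        )
        out[idx] = -d if m[idx] else d
    return out


def test_sdm_worked_examples():
    assert np.array_equal(signed_distance_map(np.array([[0, 0, 1, 0, 0]])),
                          np.array([[2.0, 1.0, 0.0, 1.0, 2.0]]))
    assert np.array_equal(signed_distance_map(np.array([[0, 1, 1, 0]])),
                          np.array([[1.0, 0.0, 0.0, 1.0]]))


@pytest.mark.parametrize("mask", [np.zeros((3, 3)), np.ones((3, 3))])
def test_sdm_uniform_masks_rejected(mask):
    with pytest.raises(ValueError, match="boundary undefined"):
        signed_distance_map(mask.astype(int))


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    rows=st.integers(1, 6),
    cols=st.integers(1, 6),
    bits=st.integers(0, 2**36 - 1),
)
def test_sdm_matches_exhaustive_search_on_small_grids(rows, cols, bits):
    mask = np.array([(bits >> i) & 1 for i in range(rows * cols)]).reshape(rows, cols)
    fg = mask.sum()
    if fg == 0 or fg == mask.size:
        return  # boundary undefined; covered by the rejection test
    assert np.allclose(signed_distance_map(mask), brute_force_sdm(mask))


# -------------------------------------------------------------- boundary loss
def test_boundary_loss_worked_examples():
    phi = np.array([[2.0, 1.0, 0.0, 1.0, 2.0]])
    assert boundary_loss(np.zeros((1, 5)), phi) == 0.0
    assert boundary_loss(np.ones((1, 5)), phi) == pytest.approx(1.2)
    # prediction identical to the ground-truth region: loss is exactly 0
    assert boundary_loss(np.array([[0, 0, 1, 0, 0]], dtype=float), phi) == 0.0
    assert boundary_loss(np.ones((1, 5)), phi, reduction="sum") == pytest.approx(6.0)


def test_boundary_loss_minimized_by_the_true_region(rng):
    mask = np.zeros((7, 7), dtype=int)
    mask[2:5, 2:5] = 1
    phi = signed_distance_map(mask)
    best = boundary_loss(mask.astype(float), phi)
    for _ in range(100):
        candidate = rng.random((7, 7))
        assert boundary_loss(candidate, phi) >= best
    # the indicator of the true region attains the analytic minimum
    assert best == pytest.approx(np.where(phi < 0, phi, 0.0).mean())


# -------------------------------------------------------------- composite loss
def test_composite_loss_limits_and_affine_combination(rng):
    mask = np.zeros((6, 6), dtype=int)
    mask[1:4, 2:5] = 1
    pred = rng.random((6, 6))
    phi = signed_distance_map(mask)
    d = dice_loss(pred, mask)
    b = boundary_loss(pred, phi)
    assert composite_loss(pred, mask, LossConfig(alpha=1.0)) == pytest.approx(d)
    assert composite_loss(pred, mask, LossConfig(alpha=0.0)) == pytest.approx(b)
    for alpha in (0.1, 0.3, 0.9):
        expected = alpha * d + (1 - alpha) * b
        assert composite_loss(pred, mask, LossConfig(alpha=alpha)) == pytest.approx(expected)


def test_composite_loss_worked_arithmetic():
    # α=0.1 with L_Dice = 0.5 and L_BD = −0.2 must give −0.13
    assert 0.1 * 0.5 + (1 - 0.1) * (-0.2) == pytest.approx(-0.13)
    mask = np.array([[0, 1, 1, 0]])
    phi = signed_distance_map(mask)
    pred = np.array([[0.0, 1.0, 1.0, 0.0]])
    assert composite_loss(pred, mask, LossConfig(alpha=0.1)) == pytest.approx(0.0)


# ----------------------------------------------------------- Wasserstein losses
def test_critic_loss_examples_and_antisymmetry(rng):
    assert critic_loss([1.0, 1.0], [0.0, 0.0]) == -1.0
    assert critic_loss([0.0], [1.0]) == 1.0
    assert critic_loss([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0)
    real, fake = rng.normal(size=5), rng.normal(size=5)
    assert critic_loss(real, fake) == pytest.approx(-critic_loss(fake, real))
    with pytest.raises(ValueError, match="empty"):
        critic_loss([], [1.0])


def test_generator_adv_loss_examples_and_monotonicity():
    assert generator_adv_loss([0.5]) == -0.5
    assert generator_adv_loss([0.0, 0.0]) == 0.0
    scores = [0.1, 0.4, -0.2]
    bumped = [0.1, 0.9, -0.2]
    assert generator_adv_loss(bumped) < generator_adv_loss(scores)


def test_loss_config_validation():
    with pytest.raises(ValueError, match="alpha"):
        LossConfig(alpha=1.5)
    with pytest.raises(ValueError, match="adv_weight"):
        LossConfig(adv_weight=-0.1)
    with pytest.raises(ValueError, match="reduction"):
        LossConfig(reduction="median")


def test_tensor_inputs_give_gradients_matching_values(rng):
    mask = np.zeros((5, 5), dtype=int)
    mask[1:4, 1:4] = 1
    pred = nn.Tensor(rng.random((5, 5)), requires_grad=True)
    loss = composite_loss(pred, mask, LossConfig(alpha=0.1))
    assert loss.item() == pytest.approx(
        composite_loss(pred.data, mask, LossConfig(alpha=0.1)))
    loss.backward()
    assert pred.grad is not None and np.all(np.isfinite(pred.grad))
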