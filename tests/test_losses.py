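"""Loss family: smoothed Dice, focal Dice, boundary residual, hybrid."""

import numpy as np
import pytest

from cpseg.losses import (
    BatchPair,
    LossConfig,
    boundary_residual,
    dice_loss,
    dice_per_label,
    disk_offsets,
    focal_dice_loss,
    hybrid_loss,
)
from cpseg.nn import Tensor

from conftest import brute_force_erosion

EPS = 1e-5


def _pair_from_binary(g1: np.ndarray, p1: np.ndarray) -> BatchPair:
    """Two-label (background + foreground) pair from binary masks."""
    g = np.stack([1.0 - g1, g1])[None].astype(np.float32)
    p = np.stack([1.0 - p1, p1])[None].astype(np.float32)
    return BatchPair(g, p)


class TestDice:
    def test_perfect_overlap_is_one(self):
        g1 = np.zeros((8, 8), np.float32)
        g1[2:6, 2:6] = 1
        d = dice_per_label(_pair_from_binary(g1, g1)).data
        np.testing.assert_allclose(d, 1.0, atol=1e-5)

    def test_disjoint_is_zero(self):
        g1 = np.zeros((8, 8), np.float32)
        p1 = np.zeros((8, 8), np.float32)
        g1[0, :4], p1[7, :4] = 1, 1
        d = dice_per_label(_pair_from_binary(g1, p1)).data[1]
        assert d == pytest.approx(0.0, abs=1e-4)

    def test_hand_counted_half_overlap(self):
        """|g|=4, |p|=4, overlap 2 -> D = (2*2)/(4+4) = 0.5."""
        g1 = np.zeros((4, 4), np.float32)
        p1 = np.zeros((4, 4), np.float32)
        g1[0, :4] = 1
        p1[0, 2:], p1[1, :2] = 1, 1
        pair = _pair_from_binary(g1, p1)
        assert dice_per_label(pair).data[1] == pytest.approx(0.5, abs=1e-4)
        cfg = LossConfig(kind="dice", include_background=False)
        assert dice_loss(pair, cfg).item() == pytest.approx(0.5, abs=1e-4)

    def test_loss_decreases_with_overlap(self):
        cfg = LossConfig(kind="dice", include_background=False)
        losses = []
        for overlap in range(5):
            g1 = np.zeros((8, 8), np.float32)
            p1 = np.zeros((8, 8), np.float32)
            g1[0, :4] = 1
            p1[0, 4 - overlap : 4] = 1
            p1[1, : 4 - overlap] = 1
            losses.append(dice_loss(_pair_from_binary(g1, p1), cfg).item())
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_matches_integer_oracle_100_trials(self):
        """Smoothed Dice equals the integer-count formula on binary pairs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            g1 = (rng.random((8, 8)) > 0.5).astype(np.float32)
            p1 = (rng.random((8, 8)) > 0.5).astype(np.float32)
            d = dice_per_label(_pair_from_binary(g1, p1)).data[1]
            inter, total = int((g1 * p1).sum()), int(g1.sum() + p1.sum())
            expected = (2 * inter + EPS) / (total + EPS)
            assert d == pytest.approx(expected, abs=1e-6)


class TestFocal:
    def test_zero_at_perfect_dice(self):
        g1 = np.zeros((8, 8), np.float32)
        g1[3:5] = 1
        assert focal_dice_loss(_pair_from_binary(g1, g1)).item() == pytest.approx(0.0, abs=1e-3)

    def test_closed_form_at_dice_e_minus_one(self):
        """D = e^-1, gamma = 0.3 -> (-ln D)^0.3 = 1 exactly."""
        g1 = np.zeros((16, 16), np.float32)
        g1[4:12, 4:12] = 1.0
        alpha = np.exp(-1.0) / (2.0 - np.exp(-1.0))  # 2a/(1+a) = e^-1
        p1 = alpha * g1
        cfg = LossConfig(kind="focal", include_background=False)
        pair = _pair_from_binary(g1, p1)
        assert dice_per_label(pair).data[1] == pytest.approx(np.exp(-1.0), rel=1e-4)
        assert focal_dice_loss(pair, cfg).item() == pytest.approx(1.0, rel=1e-4)

    def test_two_label_closed_form(self):
        """Per-label dices {e^-1, e^-8} -> loss = mean(1, 8^0.3)."""
        d = Tensor(np.array([np.exp(-1.0), np.exp(-8.0)], np.float32))
        loss = ((-(d.clip(EPS, 1.0).log())) ** 0.3).mean().item()
        assert loss == pytest.approx((1.0 + 8.0**0.3) / 2.0, rel=1e-4)

    def test_focal_gradient_favors_weak_labels(self):
        """In the poorly-segmented regime (D below ~e^(gamma-1)), gamma = 0.3
        gives the worse label the steeper gradient, and a steeper gradient
        than the plain Dice loss would (whose slope in D is constant)."""
        d = Tensor(np.array([0.2, 0.45], np.float32), requires_grad=True)
        loss = ((-(d.clip(EPS, 1.0).log())) ** 0.3).mean()
        loss.backward()
        assert abs(d.grad[0]) > abs(d.grad[1])
        dice_slope = 0.5  # |d/dD (1 - mean(D))| with two labels
        assert abs(d.grad[0]) > dice_slope


class TestBoundaryResidual:
    def test_all_zeros_residual_zero(self):
        x = np.zeros((1, 1, 12, 12), np.float32)
        np.testing.assert_array_equal(boundary_residual(x, 7).data, 0.0)

    def test_filled_square_gives_three_pixel_frame(self):
        """Disk d=7 (radius 3) erodes a filled square by a 3-pixel frame."""
        x = np.zeros((1, 1, 26, 26), np.float32)
        x[..., 3:23, 3:23] = 1.0
        res = boundary_residual(x, 7).data[0, 0]
        inner = np.zeros((26, 26), bool)
        inner[6:20, 6:20] = True
        assert (res[inner] == 0).all()
        assert (res[3:23, 3:23][~inner[3:23, 3:23]] == 1).all()

    def test_constant_map_zero_residual_everywhere(self):
        """Replicate borders make constants fixed points of the erosion."""
        x = np.full((1, 1, 16, 16), 0.7, np.float32)
        np.testing.assert_allclose(boundary_residual(x, 7).data, 0.0, atol=1e-7)

    def test_matches_brute_force_erosion_50_trials(self):
        offs = disk_offsets(7)
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.random((32, 32)).astype(np.float32)
            res = boundary_residual(x[None, None], 7).data[0, 0]
            expected = x - brute_force_erosion(x, offs)
            np.testing.assert_allclose(res, expected, atol=1e-7)

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError):
            boundary_residual(np.zeros((1, 1, 8, 8), np.float32), 6)
        with pytest.raises(ValueError):
            LossConfig(kernel_diameter=4)


class TestHybrid:
    def test_perfect_prediction_zero(self):
        g1 = np.zeros((16, 16), np.float32)
        g1[5:11, 5:11] = 1
        assert hybrid_loss(_pair_from_binary(g1, g1)).item() == pytest.approx(0.0, abs=1e-3)

    def test_lambda_zero_equals_focal(self):
        rng = np.random.default_rng(1)
        g1 = (rng.random((16, 16)) > 0.6).astype(np.float32)
        p_raw = rng.random((16, 16)).astype(np.float32)
        cfg0 = LossConfig(lam=0.0)
        pair = _pair_from_binary(g1, p_raw)
        assert hybrid_loss(pair, cfg0).item() == pytest.approx(
            focal_dice_loss(pair, cfg0).item(), rel=1e-6
        )

    def test_boundary_error_penalized_more_than_interior(self):
        """Perturbing a ring's boundary raises the hybrid loss more than an
        equal-volume interior perturbation of the same prediction."""
        g1 = np.zeros((32, 32), np.float32)
        g1[8:24, 8:24] = 1
        g1[12:20, 12:20] = 0  # ring
        edge_pix = [(8, j) for j in range(8, 16)]
        core_pix = [(10, j) for j in range(10, 18)]
        p_edge, p_core = g1.copy(), g1.copy()
        for i, j in edge_pix:
            p_edge[i, j] = 0
        for i, j in core_pix:
            p_core[i, j] = 0
        l_edge = hybrid_loss(_pair_from_binary(g1, p_edge)).item()
        l_core = hybrid_loss(_pair_from_binary(g1, p_core)).item()
        assert l_edge > l_core


@pytest.mark.parametrize("loss_fn,cfg", [
    (dice_loss, LossConfig(kind="dice")),
    (focal_dice_loss, LossConfig(kind="focal")),
    (hybrid_loss, LossConfig(kind="hybrid")),
    (hybrid_loss, LossConfig(kind="hybrid", include_background=False)),
])
def test_analytic_gradients_match_finite_differences(loss_fn, cfg):
    """Central finite differences vs tape gradients on random 8x8 pairs."""
    rng = np.random.default_rng(5)
    g1 = (rng.random((8, 8)) > 0.5).astype(np.float32)
    g = np.stack([1 - g1, g1])[None]
    p_data = rng.uniform(0.1, 0.9, size=(1, 2, 8, 8)).astype(np.float32)
    p = Tensor(p_data, requires_grad=True)
    loss = loss_fn(BatchPair(g, p), cfg)
    loss.backward()
    analytic = p.grad.copy()
    check = [(0, 0, 2, 3), (0, 1, 4, 4), (0, 1, 0, 0), (0, 0, 7, 7)]
    for idx in check:
        h = 1e-3
        pp = p_data.copy(); pp[idx] += h
        pm = p_data.copy(); pm[idx] -= h
        lp = loss_fn(BatchPair(g, Tensor(pp)), cfg).item()
        lm = loss_fn(BatchPair(g, Tensor(pm)), cfg).item()
        numeric = (lp - lm) / (2 * h)
        assert analytic[idx] == pytest.approx(numeric, abs=2e-4)


def test_batch_pair_validation():
    g = np.zeros((1, 2, 4, 4), np.float32)
    g[:, 0] = 1
    BatchPair(g, g).validate()
    with pytest.raises(ValueError):
        BatchPair(g, np.zeros((1, 3, 4, 4), np.float32))
    bad = g.copy()
    bad[:, 0, 0, 0] = 0.4
    with pytest.raises(ValueError):
        BatchPair(bad, g).validate()
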