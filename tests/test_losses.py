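import numpy as np
import pytest

from vesselseg.autodiff import Tensor
from vesselseg.errors import DimensionError
from vesselseg.losses import (
    LossConfig,
    ce_loss,
    clip_haus_directed,
    clip_haus_loss,
    dice_loss,
    epsilon_cap,
    soft_clip_haus,
    total_loss,
)


def brute_force_directed(X, Y, eps, distance="squared"):
    """Independent exhaustive-pairwise oracle."""
    X, Y = list(X), list(Y)
    if not X and not Y:
        return 0.0
    if not X or not Y:
        return float(eps)
    worst = 0.0
    for x in X:
        best = min((x[0] - y[0]) ** 2 + (x[1] - y[1]) ** 2 for y in Y)
        if distance == "linear":
            best = best ** 0.5
        worst = max(worst, best)
    return float(min(worst, eps))


def random_mask_pair(rng):
    h, w = rng.integers(1, 13, size=2)
    density = rng.uniform(0.0, 0.6)
    P = (rng.random((h, w)) < density).astype(np.uint8)
    G = (rng.random((h, w)) < density).astype(np.uint8)
    return P, G


class TestEpsilonCap:
    def test_printed_example(self):
        assert epsilon_cap(448, 448, 2) == pytest.approx(448 * np.sqrt(2) / 2, rel=1e-9)

    def test_345_triangle(self):
        assert epsilon_cap(3, 4, 5) == pytest.approx(1.0)

    def test_homogeneity(self):
        assert epsilon_cap(64, 48, 3) * 2 == pytest.approx(epsilon_cap(128, 96, 3))

    @pytest.mark.parametrize("bad", [1, 0, -2])
    def test_class_count_below_two_rejected(self, bad):
        with pytest.raises(ValueError):
            epsilon_cap(3, 4, bad)


class TestDirected:
    def test_identical_sets_zero(self):
        S = [(1, 1), (2, 3)]
        assert clip_haus_directed(S, S, 10.0) == 0.0

    def test_three_four_five(self):
        assert clip_haus_directed([(0, 0)], [(3, 4)], 100.0) == 25.0

    def test_clipping_binds(self):
        eps = epsilon_cap(8, 8, 2)  # 5.657
        assert clip_haus_directed([(0, 0)], [(3, 4)], eps) == pytest.approx(eps)

    def test_empty_policies(self):
        assert clip_haus_directed([], [], 9.0) == 0.0
        assert clip_haus_directed([], [(0, 0)], 9.0) == 9.0
        assert clip_haus_directed([(0, 0)], [], 9.0) == 9.0

    @pytest.mark.parametrize("distance", ["squared", "linear"])
    def test_matches_brute_force_on_random_masks(self, distance):
        rng = np.random.default_rng(42)
        for _ in range(60):
            P, G = random_mask_pair(rng)
            eps = epsilon_cap(P.shape[0], P.shape[1], 2)
            Pc = [tuple(c) for c in np.argwhere(P > 0)]
            Gc = [tuple(c) for c in np.argwhere(G > 0)]
            got = clip_haus_directed(np.argwhere(P > 0), np.argwhere(G > 0), eps, distance)
            assert got == brute_force_directed(Pc, Gc, eps, distance)


class TestSymmetricLoss:
    def test_identical_masks_zero(self, rng):
        M = (rng.random((9, 9)) < 0.4).astype(np.uint8)
        assert clip_haus_loss(M, M) == 0.0

    def test_single_pixel_pair(self):
        P = np.zeros((100, 100), np.uint8)
        G = np.zeros((100, 100), np.uint8)
        P[0, 0] = 1
        G[3, 4] = 1
        assert clip_haus_loss(P, G, 2) == 25.0  # eps = 70.71 not binding

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            P, G = random_mask_pair(rng)
            eps = epsilon_cap(P.shape[0], P.shape[1], 2)
            assert clip_haus_loss(P, G) == clip_haus_loss(G, P)
            assert 0.0 <= clip_haus_loss(P, G) <= eps

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            clip_haus_loss(np.zeros((3, 3)), np.zeros((3, 4)))


class TestSoftSurrogate:
    def test_hard_equal_masks_zero(self, rng):
        G = (rng.random((12, 12)) < 0.3).astype(np.float32)
        val = soft_clip_haus(G, G, tau=1e-3).item()
        assert abs(val) < 1e-3

    def test_single_pixel_reduction(self):
        P = np.zeros((100, 100), np.float32)
        G = np.zeros((100, 100), np.uint8)
        P[0, 0] = 1.0
        G[3, 4] = 1
        assert soft_clip_haus(P, G, tau=1e-3).item() == pytest.approx(25.0, abs=1e-3)

    def test_matches_exact_on_hard_masks_low_temperature(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            P, G = random_mask_pair(rng)
            exact = clip_haus_loss(P, G)
            soft = soft_clip_haus(P.astype(np.float32), G, tau=1e-3).item()
            assert abs(soft - exact) < 1e-3, (P, G)

    def test_monotone_as_probs_approach_target(self):
        rng = np.random.default_rng(1)
        G = np.zeros((16, 16), np.uint8)
        G[4:12, 7:9] = 1
        p0 = rng.uniform(0.0, 0.4, G.shape).astype(np.float32)
        vals = []
        for t in np.linspace(0.0, 1.0, 8):
            p = (1 - t) * p0 + t * G.astype(np.float32)
            vals.append(soft_clip_haus(p, G, tau=1e-3).item())
        assert all(b <= a + 1e-6 for a, b in zip(vals, vals[1:]))

    def test_rejects_out_of_range_probabilities(self):
        with pytest.raises(ValueError):
            soft_clip_haus(np.full((4, 4), 1.5, np.float32), np.zeros((4, 4)))

    def test_gradient_flows_through_probs(self):
        G = np.zeros((8, 8), np.uint8)
        G[2:5, 2:5] = 1
        p = Tensor(np.full((8, 8), 0.3, np.float32), requires_grad=True)
        soft_clip_haus(p, G).backward()
        assert p.grad is not None and np.any(p.grad)


class TestPixelLosses:
    def test_dice_perfect_overlap_near_zero(self, rng):
        G = (rng.random((10, 10)) < 0.4).astype(int)
        onehot = np.eye(2, dtype=np.float32)[G]
        assert dice_loss(Tensor(onehot), onehot).item() < 1e-4

    def test_dice_disjoint_near_one(self):
        p = np.zeros((4, 4, 1), np.float32)
        g = np.zeros((4, 4, 1), np.float32)
        p[:2, :, 0] = 1
        g[2:, :, 0] = 1
        assert dice_loss(Tensor(p), g).item() == pytest.approx(1.0, abs=1e-4)

    def test_dice_half_foreground_is_one_third(self):
        g = np.zeros((6, 6, 1), np.float32)
        g[0, :4, 0] = 1.0  # area a = 4
        p = np.zeros((6, 6, 1), np.float32)
        p[0, :2, 0] = 1.0  # a/2 predicted
        assert dice_loss(Tensor(p), g).item() == pytest.approx(1.0 / 3.0, abs=1e-4)

    def test_ce_uniform_logits_is_log_nc(self):
        logits = Tensor(np.zeros((5, 5, 2), np.float32))
        G = (np.arange(25).reshape(5, 5) % 2)
        assert ce_loss(logits, G).item() == pytest.approx(np.log(2), abs=1e-6)

    def test_ce_shape_mismatch(self):
        with pytest.raises(DimensionError):
            ce_loss(Tensor(np.zeros((4, 4, 2))), np.zeros((4, 5)))


class TestTotalLoss:
    def _setup(self, rng):
        logits = Tensor(rng.standard_normal((6, 6, 2)).astype(np.float32))
        G = (rng.random((6, 6)) < 0.3).astype(int)
        return logits, G

    def test_weight_scale_invariance(self, rng):
        logits, G = self._setup(rng)
        a = total_loss(logits, G, LossConfig(10, 10, 1)).item()
        b = total_loss(logits, G, LossConfig(30, 30, 3)).item()
        assert a == pytest.approx(b, rel=1e-6)

    def test_omega3_zero_reduces_to_ce_dice(self, rng):
        logits, G = self._setup(rng)
        _, parts = total_loss(logits, G, LossConfig(10, 10, 0), return_parts=True)
        expected = (10 * parts["ce"] + 10 * parts["dice"]) / 20
        assert parts["total"] == pytest.approx(expected, rel=1e-6)
        assert parts["clip_haus"] == 0.0

    def test_unit_parts_normalize_to_one(self):
        cfg = LossConfig(10, 10, 1)
        assert (10 * 1 + 10 * 1 + 1 * 1) / (10 + 10 + 1) == pytest.approx(1.0)

    def test_perfect_hard_prediction_leaves_only_ce_floor(self):
        G = np.zeros((8, 8), int)
        G[2:5, 3:6] = 1
        big = 20.0
        logits = np.stack([(1 - G) * big, G * big], axis=-1).astype(np.float32)
        total, parts = total_loss(Tensor(logits), G, LossConfig(), return_parts=True)
        # saturated softmax: Dice and Hausdorff vanish, CE hits its floor
        assert parts["dice"] < 1e-4
        assert parts["clip_haus"] < 1e-3
        assert parts["total"] == pytest.approx(10 * parts["ce"] / 21, rel=1e-4, abs=1e-7)

    def test_all_zero_weights_rejected(self, rng):
        logits, G = self._setup(rng)
        with pytest.raises(ValueError):
            total_loss(logits, G, LossConfig(0, 0, 0))
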