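"""Loss oracles: hand-evaluated fixtures and independent brute-force checks."""

import math

import numpy as np
import pytest

from ichseg import losses
from ichseg.losses import (
    ContrastiveConfig,
    MixedLossConfig,
    RegionConfig,
    binary_ce_loss,
    dice_loss,
    global_nce_loss,
    local_nce_loss,
    mixed_dice_loss,
    multilabel_dice_loss,
    restoration_loss,
    sample_regions,
    weighted_bce_loss,
)


def brute_force_nce(z, tau=0.1, pairing=None):
    """Independent double-loop NT-Xent evaluation."""
    z = np.asarray(z, dtype=float)
    m = len(z)
    partner = np.asarray(pairing) if pairing is not None else np.arange(m) ^ 1
    u = z / np.linalg.norm(z, axis=1, keepdims=True)
    total = 0.0
    for i in range(m):
        pos = float(u[i] @ u[partner[i]]) / tau
        denom = sum(math.exp(float(u[i] @ u[k]) / tau) for k in range(m) if k != i)
        total += -pos + math.log(denom)
    return total


class TestDice:
    def test_perfect_prediction_is_zero(self):
        t = np.zeros(20)
        t[3:9] = 1
        assert dice_loss(t, t, smoothing=0) == pytest.approx(0.0)

    def test_empty_target_full_miss_is_one(self):
        p = np.zeros(10)
        p[0] = 0.7
        assert dice_loss(p, np.zeros(10), smoothing=0) == pytest.approx(1.0)

    def test_hand_evaluated_half_probability(self):
        # p = 0.5 on n pixels, t = 1: 1 - (2*0.5n)/(0.25n + n) = 0.2
        n = 16
        assert dice_loss(np.full(n, 0.5), np.ones(n), smoothing=0) == pytest.approx(0.2)

    def test_empty_empty_with_smoothing_is_zero(self):
        assert dice_loss(np.zeros(5), np.zeros(5)) == pytest.approx(0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(3), np.zeros(4))

    def test_loss_complements_overlap_dice_for_binary_predictions(self, rng):
        """For a binary prediction and s -> 0, 1 - loss equals the Dice
        overlap coefficient computed from TP/FP/FN counts."""
        p = (rng.random(40) > 0.6).astype(float)
        t = (rng.random(40) > 0.5).astype(float)
        tp = float(np.sum(p * t))
        fp = float(np.sum(p * (1 - t)))
        fn = float(np.sum((1 - p) * t))
        overlap = 2 * tp / (2 * tp + fp + fn)
        assert 1 - dice_loss(p, t, smoothing=0) == pytest.approx(overlap)


class TestMixedDice:
    def test_all_ich_slices_equals_plain_mean(self, rng):
        p = rng.random((4, 8, 8))
        t = (rng.random((4, 8, 8)) > 0.5).astype(float)
        assert t.reshape(4, -1).sum(axis=1).min() > 0
        cfg = MixedLossConfig(alpha=0.2, smoothing=0)
        expected = np.mean([dice_loss(p[i], t[i], smoothing=0) for i in range(4)])
        assert mixed_dice_loss(p, t, cfg) == pytest.approx(expected)

    def test_empty_slice_contributes_alpha(self):
        # one empty-GT slice with dice loss 1 and alpha 0.2 contributes 0.2
        p = np.full((1, 4, 4), 0.5)
        t = np.zeros((1, 4, 4))
        cfg = MixedLossConfig(alpha=0.2, smoothing=0)
        assert mixed_dice_loss(p, t, cfg) == pytest.approx(0.2)

    def test_alpha_one_is_unweighted_mean(self, rng):
        p = rng.random((6, 5, 5))
        t = (rng.random((6, 5, 5)) > 0.7).astype(float)
        a1 = mixed_dice_loss(p, t, MixedLossConfig(alpha=1.0, smoothing=0))
        expected = np.mean([dice_loss(p[i], t[i], smoothing=0) for i in range(6)])
        assert a1 == pytest.approx(expected)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            MixedLossConfig(alpha=0.0)


class TestGlobalContrastive:
    def test_single_pair_has_zero_loss(self, rng):
        z = rng.standard_normal((2, 8))
        assert global_nce_loss(z) == pytest.approx(0.0)

    @pytest.mark.parametrize("n_pairs", [2, 3, 4])
    def test_matches_brute_force_over_seeds(self, n_pairs):
        for seed in range(25):
            z = np.random.default_rng(seed).standard_normal((2 * n_pairs, 6))
            assert global_nce_loss(z) == pytest.approx(
                brute_force_nce(z), abs=1e-6
            )

    def test_scale_invariance(self, rng):
        z = rng.standard_normal((8, 5))
        assert global_nce_loss(z) == pytest.approx(global_nce_loss(10 * z))

    def test_nonnegative(self, rng):
        for seed in range(20):
            z = np.random.default_rng(seed).standard_normal((6, 4))
            assert global_nce_loss(z) >= -1e-12

    def test_zero_norm_embedding_rejected(self):
        z = np.zeros((4, 3))
        z[1:] = 1.0
        with pytest.raises(ValueError):
            global_nce_loss(z)

    def test_positive_domination_drives_loss_to_zero(self):
        """With orthogonal negatives, the loss vanishes as tau -> 0."""
        z = np.eye(4)[[0, 0, 1, 1]] * 1.0  # two identical pairs on distinct axes
        small = global_nce_loss(z, ContrastiveConfig(temperature=0.01))
        large = global_nce_loss(z, ContrastiveConfig(temperature=1.0))
        assert small < 1e-6 < large


class TestLocalContrastive:
    def test_single_region_no_negatives(self, rng):
        f1 = rng.standard_normal((4, 6, 6))
        assert local_nce_loss(f1, f1, RegionConfig(1, 2)) == pytest.approx(0.0)

    def test_orthogonal_identical_views_closed_form(self):
        # 4 one-hot region descriptors, identical across views
        corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        c = 8
        f1 = np.zeros((c, 2, 2))
        for j, (r, col) in enumerate(corners):
            f1[j, r, col] = 1.0
        tau = 0.1
        nr = 4
        expected = 2 * nr * -math.log(
            math.exp(1 / tau) / (math.exp(1 / tau) + (2 * nr - 2))
        )
        got = local_nce_loss(
            f1, f1.copy(), RegionConfig(nr, 1), ContrastiveConfig(tau), corners=corners
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_on_descriptors(self):
        rcfg = RegionConfig(n_regions=5, region_size=2)
        for seed in range(25):
            g = np.random.default_rng(seed)
            f1 = g.standard_normal((3, 8, 8))
            f2 = g.standard_normal((3, 8, 8))
            corners = sample_regions((8, 8), rcfg, np.random.default_rng(seed + 1))
            k = rcfg.region_size
            d = []
            for r, c in corners:
                d.append(f1[:, r : r + k, c : c + k].reshape(-1))
                d.append(f2[:, r : r + k, c : c + k].reshape(-1))
            got = local_nce_loss(f1, f2, rcfg, corners=corners)
            assert got == pytest.approx(brute_force_nce(np.stack(d)), abs=1e-6)

    def test_sampled_regions_never_overlap(self):
        rcfg = RegionConfig(n_regions=6, region_size=3)
        for seed in range(300):
            corners = sample_regions((12, 12), rcfg, np.random.default_rng(seed))
            k = rcfg.region_size
            cells = set()
            for r, c in corners:
                for dr in range(k):
                    for dc in range(k):
                        assert (r + dr, c + dc) not in cells
                        cells.add((r + dr, c + dc))

    def test_region_budget_exceeding_area_rejected(self):
        with pytest.raises(ValueError):
            sample_regions((4, 4), RegionConfig(3, 3), np.random.default_rng(0))


class TestRestorationAndClassification:
    def test_restoration_zero_and_offset(self, rng):
        x = rng.random((5, 5))
        assert restoration_loss(x, x) == pytest.approx(0.0)
        assert restoration_loss(x + 0.3, x) == pytest.approx(0.09)

    def test_restoration_matches_oracle(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        assert restoration_loss(a, b) == pytest.approx(float(np.mean((a - b) ** 2)))

    def test_multilabel_dice_hand_value(self):
        q = np.full(7, 0.5)
        y = np.zeros(7)
        y[0] = 1
        # 1 - (2*0.5)/(7*0.25 + 1) = 1 - 1/2.75
        assert multilabel_dice_loss(q, y, smoothing=0) == pytest.approx(1 - 1 / 2.75)

    def test_multilabel_dice_perfect_and_permutation_invariant(self, rng):
        y = np.array([0.0, 1, 1, 0, 0, 1, 0])
        assert multilabel_dice_loss(y, y, smoothing=0) == pytest.approx(0.0)
        q = rng.random(7)
        perm = np.random.default_rng(0).permutation(7)
        assert multilabel_dice_loss(q, y, smoothing=0) == pytest.approx(
            multilabel_dice_loss(q[perm], y[perm], smoothing=0)
        )

    def test_weighted_bce_uniform_weights_is_plain_mean(self, rng):
        q = rng.uniform(0.05, 0.95, size=(4, 7))
        y = (rng.random((4, 7)) > 0.5).astype(float)
        plain = -np.mean(y * np.log(q) + (1 - y) * np.log(1 - q))
        assert weighted_bce_loss(q, y) == pytest.approx(plain)

    def test_weighted_bce_matches_oracle(self, rng):
        q = rng.uniform(0.05, 0.95, size=(3, 7))
        y = (rng.random((3, 7)) > 0.5).astype(float)
        w = rng.uniform(0.5, 2.0, size=7)
        expected = float(
            np.mean(w * -(y * np.log(q) + (1 - y) * np.log(1 - q)))
        )
        assert weighted_bce_loss(q, y, w) == pytest.approx(expected)

    def test_binary_ce_uniform_is_log2(self):
        probs = np.full((6, 2), 0.5)
        labels = np.array([0, 1, 0, 1, 1, 0])
        assert binary_ce_loss(probs, labels) == pytest.approx(math.log(2))

    def test_binary_ce_perfect_is_near_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert binary_ce_loss(probs, np.array([0, 1])) < 1e-6

    def test_binary_ce_matches_oracle(self, rng):
        p1 = rng.uniform(0.1, 0.9, size=5)
        probs = np.stack([1 - p1, p1], axis=1)
        labels = (rng.random(5) > 0.5).astype(int)
        expected = float(np.mean([-math.log(probs[i, labels[i]]) for i in range(5)]))
        assert binary_ce_loss(probs, labels) == pytest.approx(expected)


class TestGradients:
    """Analytic gradients used by the trainers agree with finite differences."""

    def test_dice_gradient(self, rng):
        p = rng.uniform(0.1, 0.9, size=12)
        t = (rng.random(12) > 0.5).astype(float)
        _, g = losses.dice_loss_grad(p, t)
        eps = 1e-6
        for i in range(0, 12, 3):
            p2 = p.copy()
            p2[i] += eps
            fd = (dice_loss(p2, t) - dice_loss(p, t)) / eps
            assert g[i] == pytest.approx(fd, abs=1e-4)

    def test_global_nce_gradient(self, rng):
        z = rng.standard_normal((6, 4))
        _, dz = losses.global_nce_loss_grad(z)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (5, 1)]:
            z2 = z.copy()
            z2[idx] += eps
            fd = (global_nce_loss(z2) - global_nce_loss(z)) / eps
            assert dz[idx] == pytest.approx(fd, abs=1e-4)

    def test_mixed_dice_gradient(self, rng):
        p = rng.uniform(0.1, 0.9, size=(3, 4, 4))
        t = np.zeros((3, 4, 4))
        t[0, 1:3, 1:3] = 1
        cfg = MixedLossConfig(alpha=0.2)
        _, g = losses.mixed_dice_loss_grad(p, t, cfg)
        eps = 1e-6
        for idx in [(0, 1, 1), (1, 0, 0), (2, 3, 3)]:
            p2 = p.copy()
            p2[idx] += eps
            fd = (mixed_dice_loss(p2, t, cfg) - mixed_dice_loss(p, t, cfg)) / eps
            assert g[idx] == pytest.approx(fd, abs=1e-4)
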