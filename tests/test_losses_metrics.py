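"""Loss and metric oracles: hand-computed cross-entropy/Dice values, the
DSC/IOU algebraic identity, and HD95 against an exhaustive pairwise
boundary-distance oracle."""

import numpy as np
import pytest

from m3seg.autodiff import Tensor
from m3seg.config import ConfigurationError, LossConfig
from m3seg.losses import ce_loss, dice_loss, one_hot, total_loss
from m3seg.metrics import dsc, evaluate_case, hd95, iou


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        y = one_hot(np.array([[0, 1], [1, 0]]), 2)
        assert ce_loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_two_class_is_ln2(self):
        y = one_hot(np.array([[0, 1]]), 2)
        p = np.full_like(y, 0.5)
        assert ce_loss(p, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_computed_two_pixel_value(self):
        # -1/2 (log 0.8 + log 0.6) = 0.36700...
        p = np.array([[0.8, 0.2], [0.4, 0.6]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert ce_loss(p, y) == pytest.approx(-(np.log(0.8) + np.log(0.6)) / 2, abs=1e-12)
        assert ce_loss(p, y) == pytest.approx(0.3670, abs=1e-4)

    def test_zero_probability_at_true_class_stays_finite(self):
        p = np.array([[0.0, 1.0]])
        y = np.array([[1.0, 0.0]])
        assert np.isfinite(ce_loss(p, y))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="differ"):
            ce_loss(np.ones((2, 2)) / 2, np.ones((3, 2)))


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        y = one_hot(np.array([[0, 1, 2], [2, 1, 0]]), 3)
        cfg = LossConfig()
        assert dice_loss(y, y, cfg) <= 2 * cfg.smooth

    def test_disjoint_masks_near_one(self):
        y = one_hot(np.array([[1, 1, 0, 0]]), 2)
        p = one_hot(np.array([[0, 0, 1, 1]]), 2).astype(float)
        assert dice_loss(p, y) == pytest.approx(1.0, abs=1e-4)

    def test_half_overlap_hand_value(self):
        # |P| = |G| = 2, overlap 1 -> dice 2*1/4 -> loss 0.5
        y = one_hot(np.array([[1, 1, 0, 0]]), 2)
        p = one_hot(np.array([[1, 0, 1, 0]]), 2).astype(float)
        assert dice_loss(p, y) == pytest.approx(0.5, abs=1e-4)

    def test_background_only_class_count_raises(self):
        y = one_hot(np.array([[0, 0]]), 1)
        with pytest.raises(ConfigurationError, match="foreground"):
            dice_loss(y, y)

    def test_monotone_in_foreground_mass(self):
        """Moving predicted mass onto the true foreground lowers the loss."""
        y = one_hot(np.array([[1, 1, 0, 0]]), 2)
        losses = []
        for t in np.linspace(0.05, 0.95, 10):
            p = np.empty_like(y, dtype=float)
            p[1, 0, :] = [t, t, 1 - t, 1 - t]
            p[0, 0, :] = 1 - p[1, 0, :]
            losses.append(dice_loss(p, y))
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestTotalLoss:
    def test_weighted_combination(self, rng):
        p = rng.dirichlet(np.ones(3), size=(2, 8)).transpose(0, 2, 1).reshape(2, 3, 4, 2)
        y = one_hot(rng.integers(0, 3, size=(2, 4, 2)), 3)
        cfg = LossConfig()
        expected = 0.5 * (ce_loss(p, y) + dice_loss(p, y, cfg))
        assert total_loss(p, y, cfg) == pytest.approx(expected, rel=1e-15)

    def test_perfect_prediction_below_smoothing(self):
        y = one_hot(np.array([[0, 1], [1, 1]]), 2)
        cfg = LossConfig()
        assert total_loss(y, y, cfg) <= cfg.smooth

    def test_gradient_finite_on_simplex_interior(self, rng):
        p = Tensor(rng.dirichlet(np.ones(3), size=8), requires_grad=True)
        y = one_hot(rng.integers(0, 3, size=8), 3)
        total_loss(p, y).backward()
        assert np.isfinite(p.grad).all()


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

class TestOverlapMetrics:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        assert dsc(m, m) == 100.0
        assert iou(m, m) == 1.0
        assert hd95(m, m) == 0.0

    def test_disjoint_and_empty_conventions(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dsc(a, b) == 0.0
        empty = np.zeros((4, 4), bool)
        assert dsc(empty, empty) == 100.0
        assert iou(empty, empty) == 1.0
        assert np.isnan(hd95(a, empty))

    def test_half_overlap_and_third_union(self):
        a = np.array([[1, 1, 0]], dtype=bool)
        b = np.array([[0, 1, 1]], dtype=bool)
        assert dsc(a, b) == pytest.approx(50.0)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_dsc_iou_identity_on_random_masks(self, rng):
        """DSC = 2*IOU/(1+IOU) for every mask pair."""
        for _ in range(1000):
            a = rng.random((6, 6)) > 0.5
            b = rng.random((6, 6)) > 0.5
            i = iou(a, b)
            assert dsc(a, b) / 100.0 == pytest.approx(2 * i / (1 + i), abs=1e-12)

    def test_symmetry(self, rng):
        a = rng.random((8, 8)) > 0.6
        b = rng.random((8, 8)) > 0.6
        assert dsc(a, b) == dsc(b, a)
        assert iou(a, b) == iou(b, a)
        if a.any() and b.any():
            assert hd95(a, b) == hd95(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="differ"):
            dsc(np.ones((2, 2), bool), np.ones((3, 3), bool))


def oracle_hd95(p, g, spacing):
    """Exhaustive pairwise-distance oracle over boundary voxels."""
    from m3seg.metrics import _boundary

    pb = np.argwhere(_boundary(p)) * np.asarray(spacing)
    gb = np.argwhere(_boundary(g)) * np.asarray(spacing)
    dmat = np.linalg.norm(pb[:, None, :] - gb[None, :, :], axis=-1)
    pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
    return np.percentile(pooled, 95)


class TestHD95:
    @pytest.mark.parametrize("spacing,axis,expected", [((1, 1), 0, 1.0),
                                                       ((1, 2), 1, 2.0),
                                                       ((1, 2), 0, 1.0)])
    def test_single_pixel_offset_matches_spacing(self, spacing, axis, expected):
        p = np.zeros((5, 5), bool)
        g = np.zeros((5, 5), bool)
        p[2, 2] = True
        pos = [2, 2]
        pos[axis] += 1
        g[tuple(pos)] = True
        assert hd95(p, g, spacing) == pytest.approx(expected)
        assert oracle_hd95(p, g, spacing) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((12, 12)) > 0.7
        g = rng.random((12, 12)) > 0.7
        if not (p.any() and g.any()):
            pytest.skip("degenerate draw")
        spacing = (1.0, 2.5)
        assert hd95(p, g, spacing) == pytest.approx(oracle_hd95(p, g, spacing), abs=1e-9)

    def test_3d_equals_stacked_2d_for_in_plane_structures(self):
        """A single-slice volume scores identically in 2-D and 3-D."""
        p2 = np.zeros((6, 6), bool)
        g2 = np.zeros((6, 6), bool)
        p2[2:4, 2:4] = True
        g2[3:5, 2:4] = True
        h2 = hd95(p2, g2, (1.0, 1.0))
        h3 = hd95(p2[None], g2[None], (1.0, 1.0, 1.0))
        assert h2 == pytest.approx(h3)


class TestEvaluateCase:
    def test_ground_truth_against_itself(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[2:5, 2:5] = 1
        mask[6:9, 6:9] = 2
        rep = evaluate_case(mask, mask, num_classes=3)
        assert set(rep.per_class) == {1, 2}
        for m in rep.per_class.values():
            assert m["dsc"] == 100.0 and m["iou"] == 1.0 and m["hd95"] == 0.0
        assert rep.mean_dsc == 100.0 and rep.hd95_undefined == 0

    def test_all_background_prediction_flags_undefined_hd95(self):
        truth = np.zeros((8, 8), dtype=int)
        truth[2:6, 2:6] = 1
        pred = np.zeros_like(truth)
        rep = evaluate_case(pred, truth, num_classes=2)
        assert rep.per_class[1]["dsc"] == 0.0
        assert np.isnan(rep.per_class[1]["hd95"])
        assert rep.hd95_undefined == 1
        assert np.isnan(rep.mean_hd95)

    def test_absent_class_skipped(self):
        mask = np.zeros((4, 4), dtype=int)
        rep = evaluate_case(mask, mask, num_classes=5)
        assert rep.per_class == {}
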