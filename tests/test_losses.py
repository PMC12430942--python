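import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgtta.core import ProbabilityMap
from dgtta.losses import DiceLossConfig, consistency_dice, tta_loss
from dgtta.spatial import AffineAugmentation, AffineRanges, consistency_mask, sample_affine, warp


def random_probs(rng, n_classes=3, shape=(6, 6, 6)):
    raw = rng.uniform(size=(n_classes, *shape))
    raw /= raw.sum(axis=0, keepdims=True)
    return ProbabilityMap(raw, list(range(n_classes)))


class TestConsistencyDice:
    def test_diagonal_zero_for_squared_exponent(self, rng):
        y = random_probs(rng)
        assert abs(consistency_dice(y, y, cfg=DiceLossConfig(exponent_d=2))) <= 1e-6

    def test_single_voxel_closed_form(self):
        e = 1e-5
        ya = ProbabilityMap(np.array([[[[0.0]]], [[[1.0]]]]), [0, 1])
        yb = ProbabilityMap(np.array([[[[1.0]]], [[[0.0]]]]), [0, 1])
        loss = consistency_dice(ya, yb, cfg=DiceLossConfig(epsilon_e=e))
        np.testing.assert_allclose(loss, 1.0 - e / (1.0 + e), atol=1e-9)

    def test_exponent_one_penalizes_soft_agreement(self):
        # identical uniform 0.5 fields: zero loss for d=2, positive for d=1
        data = np.full((2, 4, 4, 4), 0.5)
        y = ProbabilityMap(data, [0, 1])
        assert consistency_dice(y, y, cfg=DiceLossConfig(exponent_d=2)) <= 1e-6
        assert consistency_dice(y, y, cfg=DiceLossConfig(exponent_d=1)) > 0.1

    def test_symmetry_in_value(self, rng):
        ya, yb = random_probs(rng), random_probs(rng)
        assert consistency_dice(ya, yb) == pytest.approx(consistency_dice(yb, ya))

    def test_range(self, rng):
        for _ in range(5):
            ya, yb = random_probs(rng), random_probs(rng)
            loss = consistency_dice(ya, yb)
            assert -1e-6 <= loss <= 1.0 + 1e-4

    def test_monotone_decrease_toward_agreement(self, rng):
        ya, yb = random_probs(rng), random_probs(rng)
        losses = []
        for lam in np.linspace(0.0, 1.0, 5):
            mix = ProbabilityMap((1 - lam) * yb.data + lam * ya.data, [0, 1, 2])
            losses.append(consistency_dice(ya, mix))
        assert all(l1 > l2 for l1, l2 in zip(losses, losses[1:]))

    def test_empty_mask_warns_and_returns_zero(self, rng):
        ya, yb = random_probs(rng), random_probs(rng)
        with pytest.warns(UserWarning, match="empty"):
            loss = consistency_dice(ya, yb, mask=np.zeros((6, 6, 6), bool))
        assert loss == 0.0

    def test_shape_mismatch_rejected(self, rng):
        ya = random_probs(rng)
        yb = random_probs(rng, shape=(5, 6, 6))
        with pytest.raises(ValueError):
            consistency_dice(ya, yb)

    def test_mask_restricts_support(self, rng):
        # fields agreeing inside the mask give zero loss regardless of the rest
        ya, yb = random_probs(rng), random_probs(rng)
        yb.data[:, 1:5, 1:5, 1:5] = ya.data[:, 1:5, 1:5, 1:5]
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        assert consistency_dice(ya, yb, mask=mask) <= 1e-6

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DiceLossConfig(exponent_d=3)
        with pytest.raises(ValueError):
            DiceLossConfig(epsilon_e=0.0)
        with pytest.raises(ValueError):
            DiceLossConfig(class_subset=[])


class TestLossProperties:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed_a=st.integers(0, 10**6), seed_b=st.integers(0, 10**6),
           d=st.sampled_from([1, 2]))
    def test_symmetry_range_and_diagonal(self, seed_a, seed_b, d):
        """For any probability fields: value-symmetric, in [0, 1+eps], and
        (for d=2) zero on the diagonal."""
        ya = random_probs(np.random.default_rng(seed_a), shape=(4, 4, 4))
        yb = random_probs(np.random.default_rng(seed_b), shape=(4, 4, 4))
        cfg = DiceLossConfig(exponent_d=d)
        lab = consistency_dice(ya, yb, cfg=cfg)
        assert lab == pytest.approx(consistency_dice(yb, ya, cfg=cfg), abs=1e-12)
        assert -1e-9 <= lab <= 1.0 + 1e-4
        if d == 2:
            assert abs(consistency_dice(ya, ya, cfg=cfg)) <= 1e-6


class TestTTALoss:
    def test_identity_transforms_identical_outputs(self, rng):
        y = random_probs(rng, shape=(8, 8, 8))
        ident = AffineAugmentation.identity()
        assert tta_loss(y, y, ident, ident) <= 1e-6

    def test_difference_outside_mask_ignored(self, rng):
        y = random_probs(rng, shape=(10, 10, 10))
        y2 = ProbabilityMap(y.data.copy(), list(y.class_ids))
        # a translation makes a border slab invalid after inversion
        m = np.eye(4)
        m[0, 3] = 3.0
        t = AffineAugmentation(m)
        y2.data[:, 7:] = 1.0 / 3.0  # perturb only rows the inverse warp never reads
        loss = tta_loss(y, y2, t, t)
        y3 = ProbabilityMap(y.data.copy(), list(y.class_ids))
        assert loss == pytest.approx(tta_loss(y, y3, t, t), abs=1e-6)

    def test_matches_manual_composition(self, rng):
        ya = random_probs(rng, shape=(8, 8, 8))
        yb = random_probs(rng, shape=(8, 8, 8))
        ta = sample_affine(AffineRanges(), np.random.default_rng(1), (8, 8, 8))
        tb = sample_affine(AffineRanges(), np.random.default_rng(2), (8, 8, 8))
        cfg = DiceLossConfig()
        got = tta_loss(ya, yb, ta, tb, cfg)
        wa, va = warp(ya, ta, "inverse")
        wb, vb = warp(yb, tb, "inverse")
        expect = consistency_dice(wa, wb, consistency_mask(va, vb), cfg)
        assert got == pytest.approx(expect, abs=1e-12)
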