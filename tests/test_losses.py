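"""Loss definitions against closed forms and brute-force per-pixel loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paddycount as pc
from paddycount import losses
from paddycount.losses import ShapeMismatchError


class TestBce:
    def test_perfect_binary_prediction_near_zero(self, rng):
        gt = (rng.uniform(size=(16, 16)) > 0.5).astype(float)
        assert pc.bce_loss(gt, gt) <= 1e-6

    def test_uniform_half_equals_ln2(self, rng):
        gt = (rng.uniform(size=(16, 16)) > 0.5).astype(float)
        assert pc.bce_loss(np.full((16, 16), 0.5), gt) == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_per_pixel_loop(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(16, 16))
        gt = (rng.uniform(size=(16, 16)) > 0.5).astype(float)
        manual = -np.mean([gt[i, j] * np.log(pred[i, j]) + (1 - gt[i, j]) * np.log(1 - pred[i, j])
                           for i in range(16) for j in range(16)])
        assert pc.bce_loss(pred, gt) == pytest.approx(manual, abs=1e-9)

    def test_sum_reduction_scales_by_pixels(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(8, 8))
        gt = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
        assert pc.bce_loss(pred, gt, reduction="sum") == pytest.approx(
            64 * pc.bce_loss(pred, gt), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            pc.bce_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestMse:
    def test_identical_zero(self, rng):
        a = rng.normal(size=(16, 16))
        assert pc.mse_loss(a, a) == 0

    def test_constant_offset(self, rng):
        a = rng.normal(size=(16, 16))
        assert pc.mse_loss(a + 0.1, a) == pytest.approx(0.01, abs=1e-12)

    def test_matches_loop(self, rng):
        a, b = rng.normal(size=(16, 16)), rng.normal(size=(16, 16))
        manual = np.mean([(a[i, j] - b[i, j]) ** 2 for i in range(16) for j in range(16)])
        assert pc.mse_loss(a, b) == pytest.approx(manual, abs=1e-12)


class TestPnLoss:
    def test_exact_prediction_zero(self, rng):
        pts = pc.PointSet(rng.uniform(20, 100, size=(7, 2)))
        gt = pc.make_density_map(pts, (64, 64), sigma=3.0).values
        assert pc.pn_loss(gt, gt, true_count=7, p_pos=1.0) <= 1e-6

    def test_hand_worked_case(self):
        gt = np.array([[1.0, 0.0], [0.0, 0.0]])
        pred = np.array([[0.5, 0.2], [0.1, 0.0]])
        # C_O = 0.5, C_B = 0.3 -> |(1 - 0.5) - 0.3| = 0.2
        assert pc.pn_loss(pred, gt, true_count=1, p_pos=1.0) == pytest.approx(0.2, abs=1e-9)

    def test_zero_prediction_returns_true_count(self, rng):
        gt = np.abs(rng.normal(size=(8, 8)))
        assert pc.pn_loss(np.zeros((8, 8)), gt, true_count=5.0) == pytest.approx(5.0)

    def test_documented_cancellation(self):
        # undercounted positive mass exactly offset by background mass
        gt = np.array([[1.0, 0.0], [0.0, 0.0]])
        pred = np.array([[0.5, 0.5], [0.0, 0.0]])
        assert pc.pn_loss(pred, gt, true_count=1) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0, 50), st.floats(0.05, 1.0))
    def test_non_negative_and_zero_iff_balanced(self, seed, true_count, p_pos):
        rng = np.random.default_rng(seed)
        gt = np.where(rng.uniform(size=(8, 8)) > 0.7, rng.uniform(size=(8, 8)), 0)
        pred = np.abs(rng.normal(size=(8, 8)))
        loss = pc.pn_loss(pred, gt, true_count=true_count, p_pos=p_pos)
        assert loss >= 0
        # exactly zero when the positive-region mass equals the target and the
        # background is empty: (C - p*M) - (1-p)*M = C - M
        balanced = np.where(gt > 0, pred, 0.0)
        mass = balanced.sum()
        if mass > 0:
            assert pc.pn_loss(balanced * (true_count / mass), gt,
                              true_count, p_pos) == pytest.approx(0.0, abs=1e-9)


class TestTotalAndSize:
    def test_weighted_sum_default_weights(self):
        assert pc.total_loss(1.0, 2.0, 3.0, lambda_bce=0.1, gamma_si=0.1) == pytest.approx(1.5)

    def test_ablation_switch(self):
        assert pc.total_loss(1.7, 99.0, 99.0, lambda_bce=0.0, gamma_si=0.0) == 1.7

    def test_linearity(self, rng):
        m, b, s = rng.uniform(0, 5, 3)
        lam, gam = rng.uniform(0, 1, 2)
        assert pc.total_loss(2 * m, b, s, lam, gam) - pc.total_loss(m, b, s, lam, gam) \
            == pytest.approx(m, rel=1e-12)

    def test_size_loss_cases(self):
        assert pc.size_loss(8.0, 8.0) == 0
        assert pc.size_loss(10.0, 8.0) == pytest.approx(2.0)
        assert pc.size_loss(3.3, 9.1) == pc.size_loss(9.1, 3.3)


class TestGradients:
    """Analytic gradients of the training losses vs. central differences."""

    def test_mse_grad(self, rng):
        p, t = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
        g = losses.mse_grad(p, t)
        eps = 1e-6
        for ix in [(0, 0), (3, 4)]:
            pp, pm = p.copy(), p.copy()
            pp[ix] += eps
            pm[ix] -= eps
            num = (pc.mse_loss(pp, t) - pc.mse_loss(pm, t)) / (2 * eps)
            assert g[ix] == pytest.approx(num, rel=1e-5)

    def test_pn_grad(self, rng):
        gt = np.where(rng.uniform(size=(6, 6)) > 0.6, rng.uniform(size=(6, 6)), 0)
        p = np.abs(rng.normal(size=(6, 6)))
        g = losses.pn_grad(p, gt, true_count=4.0)
        eps = 1e-6
        for ix in [(1, 1), (4, 2)]:
            pp, pm = p.copy(), p.copy()
            pp[ix] += eps
            pm[ix] -= eps
            num = (pc.pn_loss(pp, gt, 4.0) - pc.pn_loss(pm, gt, 4.0)) / (2 * eps)
            assert g[ix] == pytest.approx(num, abs=1e-6)

    def test_bce_grad_wrt_logits(self, rng):
        logits = rng.normal(size=(6, 6))
        gt = (rng.uniform(size=(6, 6)) > 0.5).astype(float)
        sig = 1 / (1 + np.exp(-logits))
        g = losses.bce_grad_wrt_logits(sig, gt)
        eps = 1e-6
        for ix in [(0, 5), (2, 2)]:
            lp, lm = logits.copy(), logits.copy()
            lp[ix] += eps
            lm[ix] -= eps
            num = (pc.bce_loss(1 / (1 + np.exp(-lp)), gt)
                   - pc.bce_loss(1 / (1 + np.exp(-lm)), gt)) / (2 * eps)
            assert g[ix] == pytest.approx(num, rel=1e-4)
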