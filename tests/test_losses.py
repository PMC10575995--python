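"""Similarity, regularization, cycle and fusion losses against oracles."""

import numpy as np
import pytest

from inrreg._autodiff import Tensor
from inrreg.losses import (LossWeights, cycle_loss, fusion_loss, jacobian_det,
                           jacobian_reg, lncc_loss, ncc_loss, similarity_loss,
                           total_loss)
from inrreg.synthetic import make_analytic_field


def ncc_oracle(f, m):
    """From-scratch Pearson-correlation evaluation of |1 - NCC|."""
    f, m = f.ravel(), m.ravel()
    fc, mc = f - f.mean(), m - m.mean()
    ncc = (fc * mc).sum() / np.sqrt((fc**2).sum() * (mc**2).sum() + 1e-5)
    return abs(1.0 - ncc)


def lncc_oracle(f, m, w):
    """Naive per-window loop over all valid positions."""
    vals = []
    for i in range(f.shape[0] - w + 1):
        for j in range(f.shape[1] - w + 1):
            for k in range(f.shape[2] - w + 1):
                vals.append(ncc_oracle(f[i:i + w, j:j + w, k:k + w],
                                       m[i:i + w, j:j + w, k:k + w]))
    return float(np.mean(vals))


class TestNcc:
    def test_self_correlation_is_zero(self, rng):
        f = rng.standard_normal((6, 6, 6))
        assert ncc_loss(f, f.copy()).item() < 1e-5

    def test_positive_affine_rescale_invariance(self, rng):
        f = rng.standard_normal((6, 6, 6))
        assert ncc_loss(f, 3.5 * f + 1.2).item() < 1e-5

    def test_anticorrelated_toy_patch_gives_two(self):
        f = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        m = f[..., ::-1].copy()
        np.testing.assert_allclose(ncc_loss(f, m).item(), 2.0, atol=1e-4)

    def test_matches_from_scratch_formula_on_random_pairs(self, rng):
        for _ in range(50):
            f = rng.standard_normal((8, 8, 8))
            m = rng.standard_normal((8, 8, 8))
            np.testing.assert_allclose(
                ncc_loss(f, m).item(), ncc_oracle(f, m), atol=1e-6
            )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ncc_loss(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))


class TestLncc:
    def test_identical_patches_near_zero(self, rng):
        f = rng.standard_normal((12, 12, 12))
        assert lncc_loss(f, f.copy(), window=5).item() < 1e-4

    def test_single_window_equals_global_ncc(self, rng):
        f = rng.standard_normal((7, 7, 7))
        m = rng.standard_normal((7, 7, 7))
        np.testing.assert_allclose(
            lncc_loss(f, m, window=7).item(), ncc_loss(f, m).item(), atol=1e-10
        )

    def test_matches_naive_window_loop(self, rng):
        f = rng.standard_normal((12, 12, 12))
        m = f + 0.3 * rng.standard_normal((12, 12, 12))
        np.testing.assert_allclose(
            lncc_loss(f, m, window=5).item(), lncc_oracle(f, m, 5), atol=1e-6
        )

    def test_oversized_window_rejected(self, rng):
        with pytest.raises(ValueError):
            lncc_loss(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), window=5)


class TestSimilarity:
    def test_identical_inputs_zero_and_sum_decomposition(self, rng):
        f = rng.standard_normal((12, 12, 12))
        total, n, l = similarity_loss(f, f.copy())
        assert total.item() < 1e-4
        m = rng.standard_normal((12, 12, 12))
        total, n, l = similarity_loss(f, m)
        np.testing.assert_allclose(total.item(), n.item() + l.item(), rtol=1e-12)

    def test_monotone_under_increasing_noise(self, phantom48, rng):
        f = phantom48.image.values[8:24, 8:24, 8:24]
        losses = [
            similarity_loss(f, f + s * rng.standard_normal(f.shape))[0].item()
            for s in (0.0, 0.05, 0.2, 0.8)
        ]
        assert losses == sorted(losses)


class TestJacobianRegularizer:
    def test_identity_field_gives_exact_zero(self, rng):
        fld = make_analytic_field("identity")
        coords = rng.uniform(-1, 1, (200, 3))
        assert jacobian_reg(fld, coords).item() == 0.0

    def test_affine_field_closed_form(self, rng):
        fld = make_analytic_field("affine", matrix=np.diag([1.1, 1.0, 1.0]))
        coords = rng.uniform(-1, 1, (200, 3))
        np.testing.assert_allclose(jacobian_reg(fld, coords).item(), 0.1, atol=1e-12)

    def test_gaussian_bump_matches_analytic_jacobian(self, bump_field, rng):
        coords = rng.uniform(-1, 1, (500, 3))
        expected = np.abs(1.0 - bump_field.jacobian_determinant(coords)).mean()
        np.testing.assert_allclose(
            jacobian_reg(bump_field, coords).item(), expected, atol=1e-4
        )

    def test_network_autodiff_matches_finite_differences(self, rng):
        from tests_support import finite_difference_jacobian
        from conftest import small_net_config
        from inrreg.model import InrNetwork

        net = InrNetwork(small_net_config(seed=11))
        coords = rng.uniform(-0.8, 0.8, (100, 3))
        J_ad = net.jacobian_of_phi(coords)
        J_fd = finite_difference_jacobian(net.deform, coords, h=1e-4)
        np.testing.assert_allclose(J_ad, J_fd, atol=1e-4)


class ConstantNet:
    """Stub network displacing every coordinate by a fixed vector."""

    def __init__(self, d):
        self.d = np.asarray(d, dtype=np.float64)

    def displace_t(self, coords, with_jac=False):
        x = Tensor.as_tensor(coords)
        return x * 0.0 + self.d, None


class TestCycleLoss:
    def test_two_zero_networks_give_zero(self, rng):
        coords = rng.uniform(-1, 1, (50, 3))
        assert cycle_loss(ConstantNet([0, 0, 0]), ConstantNet([0, 0, 0]), coords).item() == 0.0

    def test_exact_inverse_shifts_give_zero(self, rng):
        coords = rng.uniform(-1, 1, (50, 3))
        d = [0.2, -0.1, 0.05]
        loss = cycle_loss(ConstantNet(d), ConstantNet([-x for x in d]), coords)
        np.testing.assert_allclose(loss.item(), 0.0, atol=1e-15)

    def test_one_sided_shift_both_residuals_carry_the_shift(self, rng):
        # forward residual d (backward net cannot undo it) and backward
        # residual d (forward net displaces the back-warped point): mean d^2
        coords = rng.uniform(-1, 1, (50, 3))
        d = np.array([0.3, 0.0, -0.4])
        loss = cycle_loss(ConstantNet(d), ConstantNet([0, 0, 0]), coords)
        np.testing.assert_allclose(loss.item(), d @ d, rtol=1e-12)


class TestFusionAndTotals:
    def test_fusion_loss_is_mean_of_similarities(self, rng):
        f = rng.standard_normal((10, 10, 10))
        a = rng.standard_normal((10, 10, 10))
        b = rng.standard_normal((10, 10, 10))
        expected = 0.5 * (similarity_loss(f, a)[0].item()
                          + similarity_loss(f, b)[0].item())
        np.testing.assert_allclose(fusion_loss(f, a, b).item(), expected, atol=1e-12)

    def test_fusion_loss_collapses_when_fused_equals_raw(self, rng):
        f = rng.standard_normal((10, 10, 10))
        a = rng.standard_normal((10, 10, 10))
        np.testing.assert_allclose(
            fusion_loss(f, a, a.copy()).item(), similarity_loss(f, a)[0].item(),
            rtol=1e-12,
        )

    def test_total_loss_arithmetic(self):
        one = Tensor(1.0)
        w = LossWeights(alpha_reg=0.1, alpha_cyc=100.0)
        parts = {"similarity": one, "regularization": one, "cycle": one,
                 "fusion": one}
        np.testing.assert_allclose(
            total_loss(parts, w, "cycle").item(), 1 + 0.1 + 100.0
        )
        np.testing.assert_allclose(total_loss(parts, w, "standard").item(), 1.1)
        np.testing.assert_allclose(total_loss(parts, w, "fusion").item(), 1.1)
        zero_w = LossWeights(alpha_reg=0.0, alpha_cyc=0.0)
        np.testing.assert_allclose(total_loss(parts, zero_w, "cycle").item(), 1.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha_reg=-0.1)


def test_jacobian_det_layout_is_transpose_safe(rng):
    A = rng.standard_normal((3, 3)) * 0.1
    J = Tensor(np.broadcast_to(A, (10, 3, 3)).copy())
    np.testing.assert_allclose(
        jacobian_det(J).data, np.linalg.det(np.eye(3) + A), rtol=1e-10
    )
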