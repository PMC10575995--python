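"""Coordinate network structure, variants and checkpointing."""

import numpy as np
import pytest

from conftest import small_net_config
from tests_support import finite_difference_jacobian
from inrreg.activations import ActivationSpec
from inrreg.model import (AffineModel, CascadeModel, EnsembleModel,
                          InrNetwork, NetworkConfig, load_checkpoint,
                          save_checkpoint)
from inrreg.synthetic import make_analytic_field


def closed_form_param_count(cfg: NetworkConfig) -> int:
    enc = 3 * (1 + 2 * cfg.n_freq)
    mid = cfg.hidden_layers // 2 if cfg.skip_at_middle else -1
    count, fan_in = 0, enc
    for layer in range(cfg.hidden_layers):
        if layer == mid and layer > 0:
            fan_in += enc
        count += fan_in * cfg.width + cfg.width
        fan_in = cfg.width
    count += fan_in * cfg.out_dim + cfg.out_dim
    return count


class TestBuild:
    def test_parameter_count_matches_closed_form(self):
        for hl, width in ((5, 256), (3, 64), (1, 16)):
            cfg = NetworkConfig(hidden_layers=hl, width=width,
                                activation=ActivationSpec(name="sine"))
            assert InrNetwork(cfg).n_parameters() == closed_form_param_count(cfg)

    def test_middle_layer_consumes_concatenated_encoding(self):
        cfg = NetworkConfig(hidden_layers=5, width=256)
        net = InrNetwork(cfg)
        assert net.weights[2].shape == (256 + 39, 256)

    def test_fresh_network_outputs_are_tiny(self, rng):
        net = InrNetwork(small_net_config(seed=4))
        x = rng.uniform(-1, 1, (1000, 3))
        assert np.abs(net.displacement(x)).max() < 0.05

    def test_same_seed_gives_identical_forward(self, rng):
        x = rng.uniform(-1, 1, (50, 3))
        a = InrNetwork(small_net_config(seed=9)).displacement(x)
        b = InrNetwork(small_net_config(seed=9)).displacement(x)
        np.testing.assert_array_equal(a, b)

    def test_trainable_omega_is_a_parameter(self):
        net = InrNetwork(small_net_config(trainable_omega=True))
        assert net.omega_t is not None and net.omega_t.item() == 30.0
        base = InrNetwork(small_net_config())
        assert net.n_parameters() == base.n_parameters() + 1


class TestDeform:
    def test_zero_last_layer_means_identity_deformation(self, rng):
        net = InrNetwork(small_net_config(seed=2))
        net.weights[-1].data[:] = 0.0
        net.biases[-1].data[:] = 0.0
        x = rng.uniform(-1, 1, (100, 3))
        np.testing.assert_array_equal(net.deform(x), x)

    def test_deform_is_coordinate_plus_displacement(self, rng):
        net = InrNetwork(small_net_config(seed=3))
        x = rng.uniform(-1, 1, (100, 3))
        np.testing.assert_allclose(net.deform(x) - net.displacement(x), x,
                                   atol=1e-12)

    def test_autodiff_jacobian_matches_finite_differences(self, rng):
        net = InrNetwork(small_net_config(seed=5))
        x = rng.uniform(-0.9, 0.9, (100, 3))
        np.testing.assert_allclose(
            net.jacobian_of_phi(x),
            finite_difference_jacobian(net.deform, x, h=1e-4),
            atol=1e-4,
        )

    @pytest.mark.parametrize("name,kw", [
        ("relu", {}), ("snake", {}), ("sine_plus", {}), ("chirp", {}),
        ("morlet", {}), ("sine_attention", {}),
        ("sine", {"trainable_omega": True}),
        ("sine", {"width_modulation": (10.0, 50.0)}),
    ])
    def test_every_activation_variant_produces_finite_fields(self, name, kw, rng):
        net = InrNetwork(small_net_config(name=name, **kw))
        x = rng.uniform(-1, 1, (64, 3))
        dx, J = net.displace_t(x, with_jac=True)
        assert np.all(np.isfinite(dx.data)) and np.all(np.isfinite(J.data))

    @pytest.mark.parametrize("name", ["morlet", "chirp", "sine_attention"])
    def test_sinusoidal_jacobians_match_finite_differences(self, name, rng):
        net = InrNetwork(small_net_config(name=name, seed=8))
        x = rng.uniform(-0.9, 0.9, (50, 3))
        np.testing.assert_allclose(
            net.jacobian_of_phi(x),
            finite_difference_jacobian(net.deform, x, h=1e-4),
            atol=1e-4,
        )


class TestEnsemble:
    def test_three_identical_members_equal_single_network(self, rng):
        nets = [InrNetwork(small_net_config(seed=7)) for _ in range(3)]
        ens = EnsembleModel(nets)
        x = rng.uniform(-1, 1, (50, 3))
        np.testing.assert_allclose(ens.displacement(x),
                                   nets[0].displacement(x), atol=1e-12)

    def test_opposite_members_average_to_zero(self, rng):
        class Shift:
            def __init__(self, d, out_dim=3):
                self.d = np.asarray(d, float)
                act = type("A", (), {"omega": 30.0})
                self.config = type("C", (), {"out_dim": 3, "activation": act})
                self.dtype = np.float64

            def displace_t(self, coords, with_jac=False):
                from inrreg._autodiff import Tensor
                x = Tensor.as_tensor(coords)
                return x * 0.0 + self.d, None

            def displacement(self, pts, chunk=0):
                return np.zeros_like(pts) + self.d

        ens = EnsembleModel([Shift([0.1, 0, 0]), Shift([-0.1, 0, 0]), Shift([0, 0, 0])])
        x = rng.uniform(-1, 1, (10, 3))
        np.testing.assert_allclose(ens.displacement(x), 0.0, atol=1e-15)

    def test_default_trio_records_omegas(self):
        ens = EnsembleModel.siren_trio(small_net_config())
        assert ens.omegas == [10.0, 30.0, 50.0]

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel([InrNetwork(small_net_config())])


class TestAffine:
    def test_identity_initialization_is_near_identity_map(self, rng):
        model = AffineModel(InrNetwork(small_net_config(seed=1)))
        x = rng.uniform(-1, 1, (100, 3))
        disp = model.displacement(x)
        assert np.abs(disp).max() < 0.05

    def test_pure_affine_jacobian_is_the_matrix(self, rng):
        model = AffineModel(InrNetwork(small_net_config(seed=1)))
        model.network.weights[-1].data[:] = 0.0
        model.network.biases[-1].data[:] = 0.0
        model.A.data = np.diag([1.1, 1.0, 1.0])
        x = rng.uniform(-1, 1, (20, 3))
        _, J = model.displace_t(x, with_jac=True)
        from inrreg.losses import jacobian_det
        np.testing.assert_allclose(jacobian_det(J).data, 1.1, rtol=1e-12)

    def test_translation_gradient_is_identity(self):
        model = AffineModel(InrNetwork(small_net_config(seed=1)))
        x = np.array([[0.2, -0.3, 0.4]])
        dx, _ = model.displace_t(x)
        dx[0, 1].backward()
        np.testing.assert_allclose(model.t.grad, [0.0, 1.0, 0.0])


class TestCascade:
    def test_zero_correction_network_reproduces_stage_one(self, rng):
        stage1 = make_analytic_field("gaussian_bump", center=(0, 0, 0),
                                     radius=0.5, amplitude=0.1)
        net2 = InrNetwork(small_net_config(seed=6))
        net2.weights[-1].data[:] = 0.0
        net2.biases[-1].data[:] = 0.0
        casc = CascadeModel(stage1, net2)
        x = rng.uniform(-1, 1, (50, 3))
        np.testing.assert_allclose(casc.displacement(x),
                                   stage1.displacement(x), atol=1e-12)

    def test_identity_stage_one_with_constant_correction(self, rng):
        stage1 = make_analytic_field("identity")
        net2 = InrNetwork(small_net_config(seed=6))
        net2.weights[-1].data[:] = 0.0
        net2.biases[-1].data[:] = 0.12
        casc = CascadeModel(stage1, net2)
        x = rng.uniform(-1, 1, (20, 3))
        np.testing.assert_allclose(casc.displacement(x) - 0.12, 0.0, atol=1e-12)

    @pytest.mark.parametrize("composed", [False, True])
    def test_cascade_jacobian_matches_finite_differences(self, composed, rng):
        stage1 = make_analytic_field("gaussian_bump", center=(0.1, 0, -0.2),
                                     radius=0.5, amplitude=0.1)
        casc = CascadeModel(stage1, InrNetwork(small_net_config(seed=6)),
                            composed=composed)
        x = rng.uniform(-0.8, 0.8, (100, 3))
        _, J = casc.displace_t(x, with_jac=True)
        J_phi = np.eye(3)[None] + np.swapaxes(J.data, 1, 2)

        def deform(pts):
            return pts + casc.displacement(pts)

        np.testing.assert_allclose(
            J_phi, finite_difference_jacobian(deform, x, h=1e-4), atol=1e-4
        )

    def test_stage_one_network_is_frozen(self):
        net1 = InrNetwork(small_net_config(seed=1))
        CascadeModel(net1, InrNetwork(small_net_config(seed=2)))
        assert all(not p.requires_grad for p in net1.parameters())


class TestCheckpoint:
    def test_round_trip_preserves_field_evaluation(self, tmp_path, rng):
        for kw in ({}, {"name": "sine_attention"}, {"trainable_omega": True}):
            net = InrNetwork(small_net_config(seed=3, **kw))
            path = tmp_path / "net.npz"
            save_checkpoint(net, path)
            net2 = load_checkpoint(path)
            x = rng.uniform(-1, 1, (50, 3))
            np.testing.assert_array_equal(net.displacement(x), net2.displacement(x))

    def test_checkpoint_reevaluates_at_other_resolution(self, tmp_path):
        net = InrNetwork(small_net_config(seed=3))
        save_checkpoint(net, tmp_path / "n.npz")
        net2 = load_checkpoint(tmp_path / "n.npz")
        assert net2.dense_field((8, 9, 10)).shape == (8, 9, 10, 3)
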