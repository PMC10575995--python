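"""Closed forms, derivatives, ranges and initialization of activations."""

import numpy as np
import pytest

from inrreg._autodiff import Tensor
from inrreg.activations import (ActivationSpec, apply_activation,
                                attention_omega, chirp, init_layer,
                                layer_omega, morlet, morlet_constants, relu,
                                sine, sine_plus, snake)


class TestClosedForms:
    def test_relu_basic_values(self):
        np.testing.assert_allclose(relu([-1.0, 0.0, 2.5]), [0.0, 0.0, 2.5])

    def test_sine_closed_form_values(self):
        assert sine(0.0) == 0.0
        np.testing.assert_allclose(sine(np.pi / 60, 30.0), 1.0)
        np.testing.assert_allclose(sine(0.1, 30.0), np.sin(3.0))

    def test_snake_closed_form_and_envelope(self):
        np.testing.assert_allclose(snake(0.0, 30.0), 2.0 / 30.0)
        np.testing.assert_allclose(snake(0.1, 30.0), 0.1 + np.cos(3.0) / 30 + 1 / 30)
        x = np.linspace(-5, 5, 1001)
        assert np.all(np.abs(snake(x, 30.0) - x) <= 2.0 / 30.0 + 1e-12)

    def test_sine_plus_closed_form(self):
        assert sine_plus(0.0) == 0.0
        np.testing.assert_allclose(sine_plus(np.pi / 30, 30.0), np.pi / 30, atol=1e-15)
        np.testing.assert_allclose(sine_plus(0.1, 30.0), 0.1 + np.sin(3.0))

    def test_chirp_closed_form_and_tanh_saturation(self):
        assert chirp(0.0) == 0.0
        np.testing.assert_allclose(
            chirp(0.05, 30.0, 10.0), np.sin(1.5 + 0.5 * np.tanh(1.5))
        )
        x = np.array([0.3, -0.3, 1.0])  # |omega x| > 8
        assert np.all(np.abs(np.abs(np.tanh(30 * x)) - 1.0) < 1e-6)

    def test_morlet_constants_large_omega_limits(self):
        a, b = morlet_constants(30.0)
        np.testing.assert_allclose(a, np.pi ** (-0.25), rtol=1e-14)
        assert b == np.exp(-450.0) and b < 1e-190  # numerically negligible

    def test_morlet_gaussian_envelope_kills_tails(self):
        assert abs(morlet(10.0, 30.0)) < 1e-20
        assert abs(morlet(-10.0, 30.0)) < 1e-20

    def test_sine_is_odd_and_morlet_odd_up_to_offset(self, rng):
        x = rng.uniform(-2, 2, 100)
        np.testing.assert_allclose(sine(-x), -sine(x), atol=1e-12)
        # b_omega ~ 1e-196 at omega=30, so the offset is numerically nil
        np.testing.assert_allclose(morlet(-x), -morlet(x), atol=1e-12)


class TestAttentionOmega:
    def test_zero_scaling_gives_center_frequency(self):
        assert attention_omega(np.ones(16), a=0.0, b=0.0) == 30.0

    def test_default_range_is_10_to_50(self):
        spec = ActivationSpec(name="sine_attention")
        assert (spec.omega0 - spec.delta_omega, spec.omega0 + spec.delta_omega) == (10.0, 50.0)

    def test_saturation_reaches_upper_bound(self):
        om = attention_omega(np.full(8, 1e6), a=1.0, b=0.0)
        np.testing.assert_allclose(om, 50.0, atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            attention_omega(np.array([]))

    def test_stays_strictly_inside_open_interval(self, rng):
        x = rng.standard_normal((2000, 8)) * 3.0
        om = attention_omega(x, a=1.0, b=-0.5)
        assert np.all(om > 10.0) and np.all(om < 50.0)


class TestEngineDerivatives:
    """Autodiff input-derivatives of each activation vs finite differences."""

    @pytest.mark.parametrize("name", ["sine", "snake", "sine_plus", "chirp", "morlet"])
    def test_propagated_derivative_matches_numeric(self, name):
        spec = ActivationSpec(name=name)
        x = np.linspace(-2, 2, 1000).reshape(-1, 1)
        z = Tensor(x)
        J = Tensor(np.ones((x.shape[0], 1, 1)))
        h, Jh = apply_activation(z, J, spec, layer_omega(spec, 1))
        eps = 1e-6
        hp, _ = apply_activation(Tensor(x + eps), None, spec, layer_omega(spec, 1))
        hm, _ = apply_activation(Tensor(x - eps), None, spec, layer_omega(spec, 1))
        numeric = (hp.data - hm.data) / (2 * eps)
        np.testing.assert_allclose(Jh.data[:, 0, 0], numeric[:, 0], atol=1e-5)

    def test_attention_derivative_includes_omega_term(self, rng):
        spec = ActivationSpec(name="sine_attention")
        a, b = Tensor(0.7), Tensor(0.1)
        x = rng.uniform(-0.5, 0.5, (50, 4))

        def forward(xv):
            h, _ = apply_activation(Tensor(xv), None, spec, None, (a, b))
            return h.data

        z = Tensor(x)
        J = Tensor(np.broadcast_to(np.eye(4)[None, :, :], (50, 4, 4)).copy())
        _, Jh = apply_activation(z, J, spec, None, (a, b))
        eps = 1e-6
        for i in range(4):
            dx = np.zeros_like(x)
            dx[:, i] = eps
            numeric = (forward(x + dx) - forward(x - dx)) / (2 * eps)
            np.testing.assert_allclose(Jh.data[:, i, :], numeric, atol=1e-5)

    def test_relu_derivative_is_step_mask(self):
        spec = ActivationSpec(name="relu")
        z = Tensor(np.array([[-1.0, 2.0]]))
        J = Tensor(np.ones((1, 1, 2)))
        _, Jh = apply_activation(z, J, spec, None)
        np.testing.assert_allclose(Jh.data[0, 0], [0.0, 1.0])


class TestInitialization:
    def test_last_layer_bound_is_1e4(self):
        for name in ("sine", "relu", "morlet"):
            w, b = init_layer(256, 3, ActivationSpec(name=name), is_last=True, seed=0)
            assert np.abs(w).max() <= 1e-4
            np.testing.assert_allclose(b, 0.0)

    def test_sine_hidden_bound_formula(self):
        rng = np.random.default_rng(0)
        w, _ = init_layer(256, 256, ActivationSpec(name="sine", omega=30.0), rng=rng)
        bound = np.sqrt(6.0 / 256) / 30.0
        assert np.abs(w).max() <= bound
        assert np.abs(w).max() > 0.8 * bound  # the bound is actually used

    def test_sine_first_layer_bound_is_one_over_fan_in(self):
        w, _ = init_layer(39, 64, ActivationSpec(name="sine"), is_first=True, seed=1)
        assert np.abs(w).max() <= 1.0 / 39

    def test_chirp_first_layer_scheme_selectable(self):
        siren = init_layer(39, 64, ActivationSpec(name="chirp"), is_first=True, seed=2)[0]
        hidden = init_layer(
            39, 64, ActivationSpec(name="chirp", first_layer_scheme="hidden"),
            is_first=True, seed=2,
        )[0]
        assert np.abs(siren).max() <= 1.0 / 39
        assert np.abs(hidden).max() <= np.sqrt(6.0 / 39) / 30.0
        assert not np.array_equal(siren, hidden)  # the schemes differ

    def test_kaiming_bound_for_non_sinusoidal(self):
        w, _ = init_layer(64, 64, ActivationSpec(name="relu"), seed=3)
        assert np.abs(w).max() <= np.sqrt(6.0 / 64)

    def test_fixed_seed_reproducible(self):
        a = init_layer(32, 16, ActivationSpec(name="sine"), seed=5)
        b = init_layer(32, 16, ActivationSpec(name="sine"), seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_width_modulation_spaces_omega_linearly(self):
        spec = ActivationSpec(name="sine", width_modulation=(10.0, 50.0))
        om = layer_omega(spec, 5)
        np.testing.assert_allclose(om, [10, 20, 30, 40, 50])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ActivationSpec(name="gabor")
        with pytest.raises(ValueError):
            ActivationSpec(name="sine", omega=-1.0)
        with pytest.raises(ValueError):
            ActivationSpec(name="relu", trainable_omega=True)
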