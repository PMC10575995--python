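"""Shared fixtures: small phantoms, analytic fields, and compact networks.

Everything is generated programmatically; training-based fixtures are
module- or session-scoped so expensive optimizations run once.
"""

import numpy as np
import pytest

import inrreg as ir
from inrreg.activations import ActivationSpec
from inrreg.model import NetworkConfig


@pytest.fixture(scope="session")
def phantom48():
    return ir.make_phantom((48, 48, 48), n_regions=5, seed=7)


@pytest.fixture(scope="session")
def bump_field():
    return ir.make_analytic_field(
        "gaussian_bump", center=(0.0, 0.0, 0.0), radius=0.7, amplitude=0.08
    )


@pytest.fixture(scope="session")
def bump_pair(phantom48, bump_field):
    """Moving/fixed pair deformed by a folding-free Gaussian bump."""
    moving, fixed, truth, ml, fl = ir.make_pair(
        phantom48, bump_field, noise_sigma=0.01, seed=1
    )
    return {"moving": moving, "fixed": fixed, "truth": truth,
            "moving_labels": ml, "fixed_labels": fl}


def small_net_config(name="sine", omega=30.0, dtype="float64", seed=0, **act_kw):
    """A compact network for CPU-scale tests."""
    return NetworkConfig(
        hidden_layers=3, width=32,
        activation=ActivationSpec(name=name, omega=omega, **act_kw),
        seed=seed, dtype=dtype,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
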